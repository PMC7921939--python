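"""Shared fixtures: small synthetic couples and template geometry."""

from __future__ import annotations

import numpy as np
import pytest

from synquant import AcquisitionSpec, SynthCoupleSpec
from synquant.synth import _tcell_mask, _truth_interface

ISO = (0.25, 0.25, 0.25)


@pytest.fixture(scope="session")
def default_spec() -> SynthCoupleSpec:
    return SynthCoupleSpec(seed=11)


@pytest.fixture(scope="session")
def coupled_cell(default_spec):
    """T cell mask and exact interface of the default coupled geometry."""
    mask = _tcell_mask(default_spec, default_spec.interface_radius, 0)
    iface = _truth_interface(default_spec, default_spec.interface_radius)
    return mask, iface, default_spec.acquisition.spacing


@pytest.fixture()
def short_acquisition() -> AcquisitionSpec:
    return AcquisitionSpec(n_frames=4)


def rot90_interface(iface, n_xy: int, pixel: float):
    """Interface geometry matching np.rot90(vol, 1, axes=(1, 2))."""
    from synquant.tracking import InterfaceGeometry

    vox = iface.voxels
    vox2 = np.column_stack([vox[:, 0], n_xy - 1 - vox[:, 2], vox[:, 1]])
    c = iface.center
    c2 = np.array([c[0], (n_xy - 1) * pixel - c[2], c[1]])
    return InterfaceGeometry(
        voxels=vox2, center=c2, normal=iface.normal, diameter=iface.diameter
    )
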