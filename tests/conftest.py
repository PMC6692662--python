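"""Shared fixtures: solved phantoms and small helper volumes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import settings

from peristim.phantom import (CurrentSourceSpec, PhantomParameters,
                              SurfacePatch, TissueLabelVolume,
                              boundary_faces, build_synthetic_head,
                              phantom_conductivities)
from peristim.volume_conductor import (FieldMaps, FieldSummary,
                                       assemble_system, field_maps,
                                       solve_potential, summarize_fields)

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@dataclass
class SolvedPhantom:
    volume: TissueLabelVolume
    source: CurrentSourceSpec
    table: dict
    system: object
    solution: object
    fields: FieldMaps
    summary: FieldSummary


def _solve_head(voxel_mm: float, rtol: float = 1e-6) -> SolvedPhantom:
    volume, source = build_synthetic_head(PhantomParameters(voxel_mm=voxel_mm))
    table = phantom_conductivities()
    system = assemble_system(volume, table, source)
    solution = solve_potential(system, rtol=rtol)
    fields = field_maps(solution, volume, table)
    summary = summarize_fields(fields, volume)
    return SolvedPhantom(volume, source, table, system, solution, fields,
                         summary)


@pytest.fixture(scope="session")
def head_2mm() -> SolvedPhantom:
    """Default phantom, default resolution, solved once per session."""
    return _solve_head(2.0)


@pytest.fixture(scope="session")
def head_4mm() -> SolvedPhantom:
    """Coarse version of the default phantom for grid-sensitivity checks."""
    return _solve_head(4.0)


def uniform_box(shape, spacing=2.0, name="tissue") -> TissueLabelVolume:
    """A fully tissue-filled box (array edges act as the insulated surface)."""
    labels = np.ones(shape, dtype=np.int16)
    return TissueLabelVolume(labels=labels, spacing=(spacing,) * 3,
                             origin=(0.0, 0.0, 0.0), names={0: "air", 1: name})


def face_patch(volume: TissueLabelVolume, axis: int, side: int,
               fraction: float = 1.0) -> SurfacePatch:
    """All boundary faces of the volume on one side of one axis."""
    faces = boundary_faces(volume)
    sel = (faces[:, 3] == axis) & (faces[:, 4] == side)
    return SurfacePatch(faces[sel], fraction)
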