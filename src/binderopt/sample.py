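"""Sampler: generate a conformational ensemble around a complex.

The role MD plays in a full-atom pipeline — relaxing the mutated complex and
producing conformations around the interaction pose to average scores over —
is filled at desk scale by a stochastic perturbation model:

* frame 1 is always the unperturbed input pose;
* each further frame applies to the *binder only* a small rigid rotation
  (uniform random axis, angle uniform in [0, rigid_rot_max]) about the binder
  anchor centroid and a random translation drawn uniformly from a ball of
  radius rigid_trans_max, then adds isotropic Gaussian noise
  (sd = residue_noise_sd) to every pseudo-atom of both partners.

Restrained sampling — the early-phase positional restraints that keep the
binding pose intact — multiplies all three amplitudes by ``restraint_factor``.
Glycine residues receive a single displacement for anchor and side so the
side==anchor invariant is preserved.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import AdapterValidationError
from .model import ComplexModel, ResidueRecord


@dataclass(frozen=True)
class SamplerParams:
    """Amplitudes of the built-in perturbation sampler.

    Units: degrees (rotation), Angstrom (translation and noise).
    ``restraint_factor`` scales every amplitude when ``restrained`` is set.
    """

    n_frames: int = 10
    rigid_rot_max: float = 5.0
    rigid_trans_max: float = 1.0
    residue_noise_sd: float = 0.3
    restrained: bool = False
    restraint_factor: float = 0.2

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError(f"n_frames must be >= 1, got {self.n_frames}")
        for name in ("rigid_rot_max", "rigid_trans_max", "residue_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.restraint_factor <= 1):
            raise ValueError(
                f"restraint_factor must lie in (0, 1], got {self.restraint_factor}"
            )

    def as_restrained(self, restrained: bool) -> "SamplerParams":
        return replace(self, restrained=restrained)


@dataclass(frozen=True)
class Ensemble:
    """Ordered conformations (frames) of one complex."""

    frames: tuple[ComplexModel, ...]
    source_params: Optional[SamplerParams]
    seed_record: int

    def __post_init__(self):
        object.__setattr__(self, "frames", tuple(self.frames))
        if not self.frames:
            raise ValueError("an ensemble needs at least one frame")
        ref = self.frames[0]
        ref_topo = [(r.chain_id, r.position, r.aa) for r in ref.residues]
        for i, f in enumerate(self.frames[1:], start=2):
            if [(r.chain_id, r.position, r.aa) for r in f.residues] != ref_topo:
                raise ValueError(f"frame {i} does not share sequence/topology with frame 1")

    def __len__(self) -> int:
        return len(self.frames)

    def binder_centroid_displacements(self) -> np.ndarray:
        """Per-frame displacement of the binder anchor centroid from frame 1 (A)."""
        c0 = self.frames[0].binder_anchor_centroid()
        return np.array([
            float(np.linalg.norm(f.binder_anchor_centroid() - c0)) for f in self.frames
        ])


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
        if n > 1e-12:
            return v / n


def jitter_sample(
    complex: ComplexModel,
    params: SamplerParams,
    rng: np.random.Generator,
    seed_record: int = -1,
) -> Ensemble:
    """Built-in sampler; see module docstring for the perturbation model.

    ``seed_record`` is carried into the ensemble for provenance only; the
    randomness comes from ``rng``.
    """
    scale = params.restraint_factor if params.restrained else 1.0
    rot_max = np.deg2rad(params.rigid_rot_max) * scale
    trans_max = params.rigid_trans_max * scale
    sd = params.residue_noise_sd * scale
    centroid = complex.binder_anchor_centroid()

    do_rigid = rot_max > 0 or trans_max > 0
    frames = [complex]
    for _ in range(params.n_frames - 1):
        axis = _random_unit(rng)
        angle = rng.uniform(0.0, rot_max)
        R = Rotation.from_rotvec(axis * angle).as_matrix()
        tdir = _random_unit(rng)
        t = tdir * trans_max * rng.uniform() ** (1.0 / 3.0)

        new_residues = []
        for r in complex.residues:
            anchor, side = r.anchor_xyz, r.side_xyz
            # zero-amplitude frames must be bit-identical to the input, so the
            # recenter-rotate-shift is skipped entirely when it is a no-op
            if do_rigid and r.chain_id in complex.binder_chains:
                anchor = R @ (anchor - centroid) + centroid + t
                side = R @ (side - centroid) + centroid + t
            if sd > 0:
                anchor = anchor + rng.normal(0.0, sd, 3)
                if r.aa == "G":
                    side = anchor
                else:
                    side = side + rng.normal(0.0, sd, 3)
            elif r.aa == "G":
                side = anchor
            new_residues.append(ResidueRecord(r.chain_id, r.position, r.aa, anchor, side))
        frames.append(complex.with_residues(new_residues))
    return Ensemble(frames=tuple(frames), source_params=params, seed_record=seed_record)


# --- external sampler adapters -------------------------------------------

#: An adapter takes (input_pdb, output_multimodel_pdb) and writes an ensemble
#: as a MODEL/ENDMDL multi-model PDB.
SamplerAdapter = Callable[[Path, Path], None]

_SAMPLER_REGISTRY: dict[str, SamplerAdapter] = {}


def register_sampler_adapter(name: str, adapter: SamplerAdapter) -> None:
    _SAMPLER_REGISTRY[name] = adapter


def _loopback_sampler(input_pdb: Path, output_pdb: Path) -> None:
    """Built-in adapter: returns the input pose as a one-frame ensemble."""
    output_pdb.write_text(
        "MODEL        1\n" + input_pdb.read_text().replace("END\n", "") + "ENDMDL\nEND\n"
    )


register_sampler_adapter("loopback", _loopback_sampler)


def external_sampler_contract(
    complex: ComplexModel, adapter_spec: str, workdir: Path | None = None
) -> Ensemble:
    """Run a registered external sampler and validate topology of each frame."""
    from .pdbio import read_ensemble, write_pdb

    if adapter_spec not in _SAMPLER_REGISTRY:
        raise KeyError(f"no sampler adapter registered under {adapter_spec!r}")
    adapter = _SAMPLER_REGISTRY[adapter_spec]
    with tempfile.TemporaryDirectory(dir=workdir) as td:
        inp = Path(td) / "input.pdb"
        out = Path(td) / "ensemble.pdb"
        write_pdb(complex, inp)
        adapter(inp, out)
        if not out.exists():
            raise AdapterValidationError(f"adapter {adapter_spec!r} produced no output file")
        try:
            frames = read_ensemble(out, binder_chains=complex.binder_chains,
                                   target_chains=complex.target_chains,
                                   mutable_positions=complex.mutable_positions)
        except Exception as exc:
            raise AdapterValidationError(
                f"adapter {adapter_spec!r} output could not be read back: {exc}"
            ) from exc
    ref = [(r.chain_id, r.position, r.aa) for r in complex.residues]
    for i, f in enumerate(frames, start=1):
        topo = [(r.chain_id, r.position, r.aa) for r in f.residues]
        if topo != ref:
            raise AdapterValidationError(
                f"adapter {adapter_spec!r} frame {i} does not match the input topology"
            )
    return Ensemble(frames=tuple(frames), source_params=None, seed_record=-1)
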