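"""Mutator: apply substitutions to the coarse-grained structure.

At this resolution a substitution changes the residue identity and leaves
coordinates untouched; side-chain repacking belongs to full-atom external
mutators, which plug in through the adapter contract below.  The only
geometric work is the glycine special case: mutating *to* glycine collapses
the side pseudo-atom onto the anchor, and mutating *from* glycine rebuilds a
pseudo C-beta 1.53 A from the anchor along a deterministic, rotation-covariant
local direction (away from the centroid of the flanking backbone anchors).
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np

from .errors import AdapterValidationError, MutationError
from .model import CB_BOND_LENGTH, ComplexModel, Mutation, ResidueRecord


def _pseudo_cb_direction(complex: ComplexModel, residue: ResidueRecord) -> np.ndarray:
    """Unit vector along which to place a rebuilt side pseudo-atom.

    Interior residues: from the centroid of the two flanking anchors toward
    the residue anchor.  Chain-terminal residues: a deterministic
    perpendicular to the single neighbour direction.  A one-residue chain
    falls back to +x.
    """
    chain = complex.chain_residues(residue.chain_id)
    idx = next(i for i, r in enumerate(chain) if r.position == residue.position)
    neighbors = [chain[i] for i in (idx - 1, idx + 1) if 0 <= i < len(chain)]
    if len(neighbors) == 2:
        centroid = (neighbors[0].anchor_xyz + neighbors[1].anchor_xyz) / 2.0
        v = residue.anchor_xyz - centroid
    elif len(neighbors) == 1:
        d = residue.anchor_xyz - neighbors[0].anchor_xyz
        v = np.cross(d, [1.0, 0.0, 0.0])
        if np.linalg.norm(v) < 1e-8:
            v = np.cross(d, [0.0, 1.0, 0.0])
    else:
        v = np.array([1.0, 0.0, 0.0])
    n = np.linalg.norm(v)
    if n < 1e-8:  # degenerate local geometry: collinear flanking anchors
        v, n = np.array([1.0, 0.0, 0.0]), 1.0
    return v / n


def apply_mutation(complex: ComplexModel, mutations: Iterable[Mutation]) -> ComplexModel:
    """Return a new complex with ``mutations`` applied; the input is untouched.

    Every mutation must hit a declared mutable position and its ``wt_aa``
    must match the current residue identity.
    """
    mut_list = list(mutations)
    muts = {(m.chain_id, m.position): m for m in mut_list}
    if len(muts) < len(mut_list):
        raise MutationError("multiple mutations address the same position")
    seq = complex.sequence()
    for (chain, pos), m in muts.items():
        if (chain, pos) not in complex.mutable_positions:
            raise MutationError(f"position {chain}:{pos} is not declared mutable")
        if seq.get((chain, pos)) != m.wt_aa:
            raise MutationError(
                f"wild-type mismatch at {chain}:{pos}: expected {m.wt_aa!r}, "
                f"found {seq.get((chain, pos))!r}"
            )
    new_residues = []
    for r in complex.residues:
        m = muts.get((r.chain_id, r.position))
        if m is None:
            new_residues.append(r)
            continue
        if m.mut_aa == "G":
            side = r.anchor_xyz
        elif r.aa == "G":
            side = r.anchor_xyz + CB_BOND_LENGTH * _pseudo_cb_direction(complex, r)
        else:
            side = r.side_xyz
        new_residues.append(ResidueRecord(r.chain_id, r.position, m.mut_aa, r.anchor_xyz, side))
    return complex.with_residues(new_residues)


# --- external mutator adapters -------------------------------------------

#: An adapter takes (input_pdb, mutation_strings, output_pdb) and writes the
#: mutated structure to output_pdb.
MutatorAdapter = Callable[[Path, list[str], Path], None]

_MUTATOR_REGISTRY: dict[str, MutatorAdapter] = {}


def register_mutator_adapter(name: str, adapter: MutatorAdapter) -> None:
    _MUTATOR_REGISTRY[name] = adapter


def shell_mutator_adapter(template: str) -> MutatorAdapter:
    """Adapter from a command template with {input}, {mutations}, {output} placeholders."""

    def run(input_pdb: Path, mutation_strs: list[str], output_pdb: Path) -> None:
        cmd = [part.format(input=str(input_pdb), mutations=",".join(mutation_strs),
                           output=str(output_pdb))
               for part in shlex.split(template)]
        subprocess.run(cmd, check=True)

    return run


def _loopback_adapter(input_pdb: Path, mutation_strs: list[str], output_pdb: Path) -> None:
    """Built-in adapter: round-trips through PDB and the internal mutator.

    The adapter interface carries no partition information, so the loopback
    infers one: chains named in the mutation strings are the binder (falling
    back to the first chain in the file), everything else the target.
    """
    from .pdbio import parse_mutation_string, read_chain_ids, read_pdb, write_pdb

    muts = [parse_mutation_string(s) for s in mutation_strs]
    chains = read_chain_ids(input_pdb)
    binder = {m.chain_id for m in muts} or {chains[0]}
    # "?" is a placeholder label satisfying the non-empty-partition invariant
    # when the file holds binder chains only; no residue ever carries it.
    target = (set(chains) - binder) or {"?"}
    model = read_pdb(
        input_pdb,
        binder_chains=binder,
        target_chains=target,
        mutable_positions={(m.chain_id, m.position) for m in muts},
    )
    write_pdb(apply_mutation(model, muts), output_pdb)


register_mutator_adapter("loopback", _loopback_adapter)


def external_mutator_contract(
    complex: ComplexModel,
    mutations: Iterable[Mutation],
    adapter_spec: str,
    workdir: Path | None = None,
) -> ComplexModel:
    """Run a registered external mutator and validate its output.

    The adapter receives a written PDB plus mutation strings and must write a
    PDB back; the result is re-read and checked for identical chain set,
    per-chain residue count, and the requested identity changes (and only
    those).  A validation failure signals a broken external tool.
    """
    from .pdbio import read_pdb, write_pdb

    if adapter_spec not in _MUTATOR_REGISTRY:
        raise KeyError(f"no mutator adapter registered under {adapter_spec!r}")
    adapter = _MUTATOR_REGISTRY[adapter_spec]
    muts = list(mutations)
    with tempfile.TemporaryDirectory(dir=workdir) as td:
        inp = Path(td) / "input.pdb"
        out = Path(td) / "output.pdb"
        write_pdb(complex, inp)
        adapter(inp, [str(m) for m in muts], out)
        if not out.exists():
            raise AdapterValidationError(f"adapter {adapter_spec!r} produced no output file")
        try:
            result = read_pdb(out, binder_chains=complex.binder_chains,
                              target_chains=complex.target_chains,
                              mutable_positions=complex.mutable_positions)
        except Exception as exc:
            raise AdapterValidationError(
                f"adapter {adapter_spec!r} output could not be read back: {exc}"
            ) from exc
    _validate_mutated(complex, result, muts, adapter_spec)
    return result


def _validate_mutated(original: ComplexModel, result: ComplexModel,
                      muts: list[Mutation], adapter_spec: str) -> None:
    orig_chains = {r.chain_id for r in original.residues}
    new_chains = {r.chain_id for r in result.residues}
    if orig_chains != new_chains:
        missing = sorted(orig_chains - new_chains)
        extra = sorted(new_chains - orig_chains)
        raise AdapterValidationError(
            f"adapter {adapter_spec!r} changed the chain set"
            + (f"; missing chains {missing}" if missing else "")
            + (f"; unexpected chains {extra}" if extra else "")
        )
    if len(result.residues) != len(original.residues):
        raise AdapterValidationError(
            f"adapter {adapter_spec!r} changed residue count "
            f"({len(original.residues)} -> {len(result.residues)})"
        )
    expected = dict(original.sequence())
    for m in muts:
        expected[(m.chain_id, m.position)] = m.mut_aa
    got = result.sequence()
    wrong = sorted(k for k in expected if expected[k] != got.get(k))
    if wrong:
        detail = ", ".join(
            f"{c}:{p} expected {expected[(c, p)]} got {got.get((c, p))}" for c, p in wrong[:5]
        )
        raise AdapterValidationError(
            f"adapter {adapter_spec!r} output has wrong residue identities: {detail}"
        )
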