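"""PDB input/output for the coarse-grained model.

The supported dialect is fixed-column wwPDB ATOM records.  Reading extracts
the alpha carbon as the backbone anchor and the beta carbon as the side-chain
pseudo-atom (falling back to CA for glycine, or with a warning for a missing
CB).  Only the first MODEL of a multi-model file is read by :func:`read_pdb`;
:func:`read_ensemble` reads all of them.  Alternate locations resolve to the
highest occupancy, then altloc 'A'.  Residues without a CA are skipped with a
warning; duplicate ``(chain, resSeq, atom, altloc)`` records and non-canonical
residue names are errors — strict validation is the point of this reader,
because adapter outputs from external tools pass through it.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .errors import PDBFormatError
from .model import (
    AA_ONE_TO_THREE,
    AA_THREE_TO_ONE,
    ComplexModel,
    Mutation,
    ResidueRecord,
)
from .sample import Ensemble

_MUTATION_RE = re.compile(r"^(?P<chain>[A-Za-z0-9]):(?P<wt>[A-Z])(?P<pos>\d+)(?P<mut>[A-Z])$")


def parse_mutation_string(s: str) -> Mutation:
    """Parse ``"A:I45W"`` into a :class:`Mutation`."""
    m = _MUTATION_RE.match(s.strip())
    if not m:
        raise ValueError(f"malformed mutation string {s!r} (expected e.g. 'A:I45W')")
    pos = int(m.group("pos"))
    if pos < 1:
        raise ValueError(f"mutation position must be >= 1 in {s!r}")
    try:
        return Mutation(m.group("chain"), pos, m.group("wt"), m.group("mut"))
    except Exception as exc:
        raise ValueError(f"invalid mutation string {s!r}: {exc}") from exc


def format_mutation(m: Mutation) -> str:
    return str(m)


def _parse_atom_line(line: str, lineno: int):
    try:
        return {
            "name": line[12:16].strip(),
            "altloc": line[16],
            "resname": line[17:20].strip(),
            "chain": line[21],
            "resseq": int(line[22:26]),
            "x": float(line[30:38]),
            "y": float(line[38:46]),
            "z": float(line[46:54]),
            "occ": float(line[54:60]) if line[54:60].strip() else 1.0,
        }
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"line {lineno}: unparseable ATOM record: {line.rstrip()!r}") from exc


def _collect_model(lines: Iterable[tuple[int, str]]):
    """Group ATOM records into residues, resolving altlocs; returns an ordered
    dict ``(chain, resseq) -> {"resname": ..., "atoms": {name: (x,y,z)}}``."""
    residues: dict[tuple[str, int], dict] = {}
    seen: set[tuple[str, int, str, str]] = set()
    candidates: dict[tuple[str, int, str], list] = {}
    for lineno, line in lines:
        a = _parse_atom_line(line, lineno)
        key = (a["chain"], a["resseq"])
        dupkey = (a["chain"], a["resseq"], a["name"], a["altloc"])
        if dupkey in seen:
            raise PDBFormatError(
                f"line {lineno}: duplicate atom {a['name']!r} (altloc {a['altloc']!r}) "
                f"in residue {a['chain']}{a['resseq']}"
            )
        seen.add(dupkey)
        if key in residues and residues[key]["resname"] != a["resname"]:
            raise PDBFormatError(
                f"line {lineno}: residue {a['chain']}{a['resseq']} has conflicting "
                f"names {residues[key]['resname']!r} and {a['resname']!r}"
            )
        residues.setdefault(key, {"resname": a["resname"]})
        candidates.setdefault((a["chain"], a["resseq"], a["name"]), []).append(
            (a["occ"], a["altloc"], (a["x"], a["y"], a["z"]))
        )
    for (chain, resseq, name), alts in candidates.items():
        # highest occupancy wins; ties resolve to altloc 'A', then lowest label
        best = sorted(alts, key=lambda c: (-c[0], c[1] != "A", c[1]))[0]
        residues[(chain, resseq)].setdefault("atoms", {})[name] = best[2]
    return residues


def _model_from_residues(
    residues: dict,
    binder_chains: Iterable[str],
    target_chains: Iterable[str],
    mutable_positions: Optional[Iterable[tuple[str, int]]],
) -> ComplexModel:
    records = []
    for (chain, resseq), info in residues.items():
        resname = info["resname"]
        if resname not in AA_THREE_TO_ONE:
            raise PDBFormatError(
                f"non-canonical residue {resname!r} at {chain}{resseq}; only the 20 "
                "standard amino acids are supported"
            )
        aa = AA_THREE_TO_ONE[resname]
        atoms = info.get("atoms", {})
        if "CA" not in atoms:
            warnings.warn(f"residue {chain}{resseq} has no CA; skipped", stacklevel=3)
            continue
        anchor = atoms["CA"]
        if aa == "G":
            side = anchor
        elif "CB" in atoms:
            side = atoms["CB"]
        else:
            warnings.warn(
                f"residue {chain}{resseq} ({resname}) has no CB; using CA as side "
                "pseudo-atom", stacklevel=3,
            )
            side = anchor
        records.append(ResidueRecord(chain, resseq, aa, anchor, side))
    mut = frozenset(mutable_positions) if mutable_positions is not None else frozenset()
    return ComplexModel(
        residues=tuple(records),
        binder_chains=frozenset(binder_chains),
        target_chains=frozenset(target_chains),
        mutable_positions=mut,
    )


def _atom_lines_by_model(path: Path) -> list[list[tuple[int, str]]]:
    models: list[list[tuple[int, str]]] = []
    current: list[tuple[int, str]] = []
    in_model = False
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        rec = line[:6]
        if rec == "MODEL ":
            in_model = True
            current = []
        elif rec == "ENDMDL":
            models.append(current)
            current = []
            in_model = False
        elif rec == "ATOM  ":
            current.append((lineno, line))
    if current or not models:
        models.append(current)
    return [m for m in models if m] or [[]]


def read_pdb(
    path: Path | str,
    binder_chains: Iterable[str],
    target_chains: Iterable[str],
    mutable_positions: Optional[Iterable[tuple[str, int]]] = None,
) -> ComplexModel:
    """Read the first model of a PDB file into a :class:`ComplexModel`."""
    models = _atom_lines_by_model(Path(path))
    if not models[0]:
        raise PDBFormatError(f"{path}: no ATOM records found")
    residues = _collect_model(models[0])
    return _model_from_residues(residues, binder_chains, target_chains, mutable_positions)


def read_ensemble(
    path: Path | str,
    binder_chains: Iterable[str],
    target_chains: Iterable[str],
    mutable_positions: Optional[Iterable[tuple[str, int]]] = None,
) -> list[ComplexModel]:
    """Read every MODEL of a (multi-model) PDB file."""
    models = _atom_lines_by_model(Path(path))
    if not any(models):
        raise PDBFormatError(f"{path}: no ATOM records found")
    return [
        _model_from_residues(_collect_model(m), binder_chains, target_chains,
                             mutable_positions)
        for m in models
    ]


def read_chain_ids(path: Path | str) -> list[str]:
    """Chain labels of the first model, in order of first appearance."""
    chains: list[str] = []
    for _, line in _atom_lines_by_model(Path(path))[0]:
        c = line[21]
        if c not in chains:
            chains.append(c)
    if not chains:
        raise PDBFormatError(f"{path}: no ATOM records found")
    return chains


def _format_atom(serial: int, name: str, resname: str, chain: str, resseq: int,
                 xyz, element: str) -> str:
    return (
        f"ATOM  {serial:5d} {name:^4s} {resname:>3s} {chain}{resseq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{element:>2s}"
    )


def _complex_atom_lines(complex: ComplexModel, start_serial: int = 1) -> list[str]:
    lines = []
    serial = start_serial
    last_chain = None
    for r in complex.residues:
        if last_chain is not None and r.chain_id != last_chain:
            lines.append("TER")
        last_chain = r.chain_id
        resname = AA_ONE_TO_THREE[r.aa]
        lines.append(_format_atom(serial, "CA", resname, r.chain_id, r.position,
                                  r.anchor_xyz, "C"))
        serial += 1
        if r.aa != "G":
            lines.append(_format_atom(serial, "CB", resname, r.chain_id, r.position,
                                      r.side_xyz, "C"))
            serial += 1
    lines.append("TER")
    return lines


def write_pdb(complex: ComplexModel, path: Path | str) -> None:
    """Write one CA (+ CB for non-glycine) pseudo-atom pair per residue."""
    lines = _complex_atom_lines(complex)
    Path(path).write_text("\n".join(lines + ["END"]) + "\n")


def write_ensemble(ensemble: Ensemble | Sequence[ComplexModel], path: Path | str) -> None:
    """Write an ensemble as a MODEL/ENDMDL multi-model PDB."""
    frames = ensemble.frames if isinstance(ensemble, Ensemble) else tuple(ensemble)
    lines: list[str] = []
    for i, frame in enumerate(frames, start=1):
        lines.append(f"MODEL     {i:4d}")
        lines.extend(_complex_atom_lines(frame))
        lines.append("ENDMDL")
    Path(path).write_text("\n".join(lines + ["END"]) + "\n")
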