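"""Cα-only protein structures: PDB parsing, helix assignment, minimal I/O.

The package works exclusively at the Cα level: one bead per residue, an
author residue number, a one-letter code and an optional set of helix
intervals.  Helices are assigned from Cα geometry alone (P-SEA-style
distance criteria) so that structures from any source — crystallographic
files or the synthetic generators — are treated identically.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

logger = logging.getLogger(__name__)

#: Chemically plausible bounds on consecutive Cα–Cα distances (Å).
CA_CA_MIN = 2.5
CA_CA_MAX = 4.5

# P-SEA-style Cα-only helix criteria (distances in Å).
_HELIX_D13 = (4.8, 5.6)   # d(i, i+3)
_HELIX_D14 = (5.0, 6.5)   # d(i, i+4)
_HELIX_MIN_LEN = 5


@dataclass(frozen=True)
class ChainSelection:
    """Which chain/model/altloc to extract from a coordinate file."""

    chain_id: str | None = None       # None = first chain encountered
    model_index: int = 0
    altloc_policy: str = "highest-occupancy"   # or "A-preferred"

    def __post_init__(self) -> None:
        if self.altloc_policy not in ("highest-occupancy", "A-preferred"):
            raise ValueError(f"unknown altloc policy {self.altloc_policy!r}")


@dataclass
class CalphaStructure:
    """One chain of one model, reduced to its Cα trace.

    Internally positions are 0-based contiguous indices; ``residue_ids``
    keeps the author numbering for reporting.  ``helices`` are half-open
    ``(start, end)`` intervals over the internal indexing.  ``chain_breaks``
    lists indices i where the (i, i+1) step exceeds :data:`CA_CA_MAX`;
    such pairs are chemically non-contiguous and downstream models must
    not treat them as bonded.
    """

    label: str
    residue_ids: list[int]
    sequence: str
    coords: np.ndarray                      # (N, 3) float Å
    helices: list[tuple[int, int]] = field(default_factory=list)
    chain_breaks: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.sequence)
        if not (len(self.residue_ids) == n == len(self.coords)):
            raise ValueError("residue_ids, sequence and coords must have equal length")
        for a, b in self.helices:
            if not (0 <= a < b <= n):
                raise ValueError(f"helix interval ({a}, {b}) out of bounds")
        for (a0, b0), (a1, b1) in zip(self.helices, self.helices[1:]):
            if a1 < b0:
                raise ValueError("helix intervals overlap")

    def __len__(self) -> int:
        return len(self.sequence)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "CalphaStructure":
        """Return a copy under the rigid motion x -> x R^T + t."""
        return replace(self, coords=self.coords @ np.asarray(rotation).T + translation)

    def to_fasta(self) -> str:
        lines = [f">{self.label}"]
        seq = self.sequence
        lines += [seq[i:i + 60] for i in range(0, len(seq), 60)]
        return "\n".join(lines) + "\n"


def _find_chain_breaks(coords: np.ndarray) -> list[int]:
    if len(coords) < 2:
        return []
    d = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    return [int(i) for i in np.nonzero(d > CA_CA_MAX)[0]]


def validate_spacing(s: CalphaStructure) -> None:
    """Check Cα–Cα spacing; breaks must be flagged, short contacts are errors."""
    if len(s) < 2:
        return
    d = np.linalg.norm(np.diff(s.coords, axis=0), axis=1)
    if np.any(d < CA_CA_MIN):
        bad = int(np.argmin(d))
        raise ValueError(
            f"{s.label}: consecutive Calpha distance {d[bad]:.2f} A at index {bad} "
            f"below {CA_CA_MIN} A"
        )
    missing = set(_find_chain_breaks(s.coords)) - set(s.chain_breaks)
    if missing:
        raise ValueError(f"{s.label}: unflagged chain breaks at {sorted(missing)}")


def _pick_altloc(atoms, policy: str):
    """Resolve a Biopython (possibly disordered) atom to one position."""
    if not atoms.is_disordered():
        return atoms
    children = list(atoms.disordered_get_list())
    if policy == "A-preferred":
        for child in children:
            if child.get_altloc() == "A":
                return child
    return max(children, key=lambda a: a.get_occupancy() or 0.0)


def read_pdb_calpha(path, selection: ChainSelection | None = None) -> CalphaStructure:
    """Parse one chain of a PDB file into a :class:`CalphaStructure`.

    Residues without a CA atom are skipped with a warning; non-standard
    residues get sequence letter 'X'.  Only the selected model is read
    (default: first).
    """
    selection = selection or ChainSelection()
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("s", str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no models found")
    if selection.model_index >= len(models):
        raise ValueError(f"{path}: model {selection.model_index} not present")
    model = models[selection.model_index]

    chains = {c.id: c for c in model}
    if selection.chain_id is None:
        chain = next(iter(chains.values()))
    elif selection.chain_id in chains:
        chain = chains[selection.chain_id]
    else:
        raise KeyError(
            f"{path}: chain {selection.chain_id!r} not found; "
            f"available chains: {sorted(chains)}"
        )

    residue_ids, letters, xyz = [], [], []
    for res in chain:
        if res.id[0] != " " and res.id[0] != "H_MSE":
            continue   # skip waters/het unless selenomethionine-like
        if "CA" not in res:
            if res.id[0] == " ":
                logger.warning("%s: residue %s%s has no CA atom, skipped",
                               path, res.get_resname(), res.id[1])
            continue
        atom = _pick_altloc(res["CA"], selection.altloc_policy)
        residue_ids.append(res.id[1])
        letters.append(protein_letters_3to1.get(res.get_resname().strip(), "X"))
        xyz.append(atom.get_coord())
    if not xyz:
        raise ValueError(f"{path}: no CA atoms in chain {chain.id!r}")

    coords = np.asarray(xyz, dtype=float)
    label = f"{getattr(path, 'stem', str(path))}_{chain.id}"
    return CalphaStructure(
        label=label,
        residue_ids=residue_ids,
        sequence="".join(letters),
        coords=coords,
        chain_breaks=_find_chain_breaks(coords),
    )


def write_pdb_calpha(structures, path) -> None:
    """Write one or more Cα structures as a minimal (multi-MODEL) PDB file."""
    if isinstance(structures, CalphaStructure):
        structures = [structures]
    one_to_three = {v: k for k, v in protein_letters_3to1.items()}
    lines = []
    multi = len(structures) > 1
    for imodel, s in enumerate(structures, start=1):
        if multi:
            lines.append(f"MODEL     {imodel:4d}")
        for iatom, (rid, aa, (x, y, z)) in enumerate(
                zip(s.residue_ids, s.sequence, s.coords), start=1):
            res3 = one_to_three.get(aa, "UNK")
            lines.append(
                f"ATOM  {iatom:5d}  CA  {res3:>3s} A{rid:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           C"
            )
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def assign_helices(s: CalphaStructure) -> CalphaStructure:
    """Detect α-helical runs from Cα geometry and return an annotated copy.

    A position i is helix-like when d(i, i+3) and d(i, i+4) fall in the
    canonical α-helix windows; runs shorter than 5 residues are dropped.
    Structures with fewer than 5 residues get an empty helix list.
    """
    n = len(s)
    helices: list[tuple[int, int]] = []
    if n >= _HELIX_MIN_LEN:
        x = s.coords
        d13 = np.linalg.norm(x[3:] - x[:-3], axis=1)
        d14 = np.linalg.norm(x[4:] - x[:-4], axis=1) if n >= 5 else np.empty(0)
        ok = np.zeros(n, dtype=bool)
        for i in range(n - 4):
            ok[i] = (_HELIX_D13[0] <= d13[i] <= _HELIX_D13[1]
                     and _HELIX_D14[0] <= d14[i] <= _HELIX_D14[1])
        # a window starting at i covers residues i..i+4
        cover = np.zeros(n, dtype=bool)
        for i in np.nonzero(ok)[0]:
            cover[i:i + 5] = True
        start = None
        for i in range(n + 1):
            at_break = i > 0 and (i - 1) in s.chain_breaks
            inside = i < n and cover[i] and not at_break
            if inside and start is None:
                start = i
            elif not inside and start is not None:
                if i - start >= _HELIX_MIN_LEN:
                    helices.append((start, i))
                start = i if (i < n and cover[i]) else None
    return replace(s, helices=helices)
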