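"""Multiple structural alignment and similarity matrices.

The aligner is a progressive structural aligner: pairwise dynamic
programming over a distance-profile score, refined by iterating
superposition on the current correspondence, then merged along an
average-linkage guide tree with the usual "once a gap, always a gap"
discipline.  An externally produced alignment (aligned FASTA, e.g. from
MUSTANG) can be imported instead, so downstream stages are agnostic to
the alignment's provenance.

Summary statistics of the similarity matrices are computed over the full
matrix including the self-comparison diagonal, matching how such tables
are conventionally reported (`summary(as.vector(m))` in R).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .structures import CalphaStructure
from .superpose import kabsch_fit, kabsch_rmsd

_GAP_PENALTY = 0.3
_D0 = 4.0          # distance scale (Å) of the superposition-based score
_PROFILE_OFFSETS = (1, 2, 3, 4, 5, 6, 8, 10)


class AlignmentError(RuntimeError):
    """Raised when no structural correspondence of useful length exists."""


# ---------------------------------------------------------------------------
# pairwise alignment

def _semiglobal_dp(score: np.ndarray, gap: float = _GAP_PENALTY):
    """Needleman–Wunsch with linear gaps and free end gaps.

    Returns the list of matched index pairs (strictly increasing in both
    sequences) and the alignment score.
    """
    n, m = score.shape
    h = np.zeros((n + 1, m + 1))
    j_arr = np.arange(m + 1) * gap
    for i in range(1, n + 1):
        a = np.empty(m + 1)
        a[0] = h[i - 1, 0]
        a[1:] = np.maximum(h[i - 1, :-1] + score[i - 1], h[i - 1, 1:] - gap)
        h[i] = np.maximum.accumulate(a + j_arr) - j_arr
    # best end point on the bottom/right boundary (free end gaps)
    bi, bj = n, int(np.argmax(h[n]))
    if np.max(h[:, m]) > h[bi, bj]:
        bi, bj = int(np.argmax(h[:, m])), m
    pairs = []
    i, j = bi, bj
    eps = 1e-9
    while i > 0 and j > 0:
        if abs(h[i, j] - (h[i - 1, j - 1] + score[i - 1, j - 1])) < eps:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif abs(h[i, j] - (h[i - 1, j] - gap)) < eps:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs, float(h[bi, bj])


def _distance_profile(coords: np.ndarray) -> np.ndarray:
    """Per-residue local-geometry descriptor: |Cα_i − Cα_{i±δ}| distances."""
    n = len(coords)
    prof = np.full((n, 2 * len(_PROFILE_OFFSETS)), np.nan)
    for k, off in enumerate(_PROFILE_OFFSETS):
        d = np.linalg.norm(coords[off:] - coords[:-off], axis=1)
        prof[:n - off, k] = d
        prof[off:, len(_PROFILE_OFFSETS) + k] = d
    return prof


def _profile_score(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    pa, pb = _distance_profile(a), _distance_profile(b)
    diff = np.abs(pa[:, None, :] - pb[None, :, :])
    valid = ~np.isnan(diff)
    mean = np.where(valid.sum(-1) > 0,
                    np.nansum(diff, axis=-1) / np.maximum(valid.sum(-1), 1),
                    10.0)
    return np.exp(-mean / 1.5)


def align_coordinates(a: np.ndarray, b: np.ndarray, max_iter: int = 20):
    """Structural correspondence between two Cα coordinate sets.

    Dynamic programming on a distance-profile score seeds a
    correspondence; superposing on it and re-scoring with
    ``1 / (1 + (d/d0)^2)`` iterates until the correspondence is stable.

    Returns ``(pairs, rmsd, score, (rotation, translation))`` with the
    transform mapping ``b`` into ``a``'s frame.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pairs, score = _semiglobal_dp(_profile_score(a, b))
    rot, trans = np.eye(3), np.zeros(3)
    for _ in range(max_iter):
        if len(pairs) < 3:
            break
        ia = np.array([p[0] for p in pairs])
        ib = np.array([p[1] for p in pairs])
        rot, trans, _ = kabsch_fit(b[ib], a[ia])
        bt = b @ rot.T + trans
        d = np.linalg.norm(a[:, None] - bt[None, :], axis=-1)
        new_pairs, score = _semiglobal_dp(1.0 / (1.0 + (d / _D0) ** 2))
        if new_pairs == pairs:
            break
        pairs = new_pairs
    if len(pairs) < 10:
        raise AlignmentError(
            f"no structural correspondence of length >= 10 found "
            f"(best: {len(pairs)})")
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    rot, trans, rmsd = kabsch_fit(b[ib], a[ia])
    return pairs, rmsd, score, (rot, trans)


def pairwise_structure_align(a: CalphaStructure, b: CalphaStructure):
    """Residue correspondence between two structures (see align_coordinates)."""
    if len(a) < 20 or len(b) < 20:
        raise ValueError("structures must have at least 20 residues")
    pairs, rmsd, score, _ = align_coordinates(a.coords, b.coords)
    return pairs, rmsd, score


# ---------------------------------------------------------------------------
# multiple alignment

@dataclass
class StructuralMSA:
    """Residue-correspondence table across structures.

    ``columns[s, c]`` is the residue index of structure ``s`` in column
    ``c``, or -1 for a gap.  Non-gap entries are strictly increasing along
    each row (correspondences never cross).
    """

    labels: list[str]
    sequences: list[str]
    columns: np.ndarray       # (S, C) int

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=int)
        for s, row in enumerate(self.columns):
            idx = row[row >= 0]
            if np.any(np.diff(idx) <= 0):
                raise ValueError(f"row {s}: residue indices not increasing")
            if idx.size and (idx.min() < 0 or idx.max() >= len(self.sequences[s])):
                raise ValueError(f"row {s}: residue index out of bounds")

    @property
    def n_structures(self) -> int:
        return self.columns.shape[0]

    @property
    def n_columns(self) -> int:
        return self.columns.shape[1]

    @property
    def occupancy(self) -> np.ndarray:
        return (self.columns >= 0).mean(axis=0)

    def full_occupancy_columns(self) -> np.ndarray:
        return np.nonzero(np.all(self.columns >= 0, axis=0))[0]

    def gapped_sequences(self) -> list[str]:
        out = []
        for seq, row in zip(self.sequences, self.columns):
            out.append("".join(seq[i] if i >= 0 else "-" for i in row))
        return out

    def to_fasta(self) -> str:
        chunks = []
        for label, gseq in zip(self.labels, self.gapped_sequences()):
            chunks.append(f">{label}")
            chunks += [gseq[i:i + 60] for i in range(0, len(gseq), 60)]
        return "\n".join(chunks) + "\n"

    @classmethod
    def from_fasta(cls, text: str, structures: list[CalphaStructure]) -> "StructuralMSA":
        """Import an externally produced aligned FASTA (e.g. MUSTANG output).

        Records are matched to structures by label; each record's
        ungapped sequence must equal the structure's sequence.
        """
        records: dict[str, str] = {}
        name = None
        for line in text.splitlines():
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                records[name] = ""
            elif name is not None and line:
                records[name] += line
        by_label = {s.label: s for s in structures}
        labels, sequences, rows = [], [], []
        for name, gseq in records.items():
            if name not in by_label:
                raise KeyError(f"alignment record {name!r} matches no structure")
            s = by_label[name]
            ungapped = gseq.replace("-", "").replace(".", "")
            if ungapped.upper() != s.sequence.upper():
                raise ValueError(f"{name}: aligned sequence disagrees with structure")
            row, k = [], 0
            for ch in gseq:
                if ch in "-.":
                    row.append(-1)
                else:
                    row.append(k)
                    k += 1
            labels.append(name)
            sequences.append(s.sequence)
            rows.append(row)
        return cls(labels=labels, sequences=sequences, columns=np.array(rows))


class _Cluster:
    """Working state of one cluster during progressive merging."""

    def __init__(self, index: int, structure: CalphaStructure):
        self.members = [index]
        self.rows = {index: np.arange(len(structure))}
        self.coords = {index: structure.coords.copy()}

    def representative(self) -> np.ndarray:
        n_cols = len(next(iter(self.rows.values())))
        rep = np.zeros((n_cols, 3))
        count = np.zeros(n_cols)
        for m in self.members:
            row = self.rows[m]
            ok = row >= 0
            rep[ok] += self.coords[m][row[ok]]
            count[ok] += 1
        count[count == 0] = 1  # cannot happen: every column has >= 1 member
        return rep / count[:, None]


def _merge_clusters(ca: _Cluster, cb: _Cluster) -> _Cluster:
    repa, repb = ca.representative(), cb.representative()
    pairs, _, _, (rot, trans) = align_coordinates(repa, repb)
    for m in cb.members:
        cb.coords[m] = cb.coords[m] @ rot.T + trans
    merged_cols: list[tuple[int, int]] = []   # (col in A or -1, col in B or -1)
    ia = ib = 0
    na, nb = len(repa), len(repb)
    for pa, pb in pairs + [(na, nb)]:
        while ia < pa:
            merged_cols.append((ia, -1)); ia += 1
        while ib < pb:
            merged_cols.append((-1, ib)); ib += 1
        if pa < na:
            merged_cols.append((pa, pb)); ia, ib = pa + 1, pb + 1
    out = _Cluster.__new__(_Cluster)
    out.members = ca.members + cb.members
    out.rows, out.coords = {}, {}
    for m in ca.members:
        row = ca.rows[m]
        out.rows[m] = np.array([row[c] if c >= 0 else -1 for c, _ in merged_cols])
        out.coords[m] = ca.coords[m]
    for m in cb.members:
        row = cb.rows[m]
        out.rows[m] = np.array([row[c] if c >= 0 else -1 for _, c in merged_cols])
        out.coords[m] = cb.coords[m]
    return out


def progressive_msa(structures: list[CalphaStructure],
                    guide: np.ndarray | None = None) -> StructuralMSA:
    """Progressive multiple structural alignment along a guide tree.

    The guide tree defaults to average linkage over pairwise alignment
    distances (1 − score/min-length).  Once two structures are merged,
    their mutual correspondence is never revised ("once a gap, always a
    gap").
    """
    n = len(structures)
    if n < 2:
        raise ValueError("need at least 2 structures")
    if guide is None:
        dist = np.zeros((n, n))
        failures = []
        for i in range(n):
            for j in range(i + 1, n):
                try:
                    _, _, score = pairwise_structure_align(structures[i],
                                                           structures[j])
                    sim = score / min(len(structures[i]), len(structures[j]))
                except AlignmentError as exc:
                    failures.append((structures[i].label, structures[j].label,
                                     str(exc)))
                    sim = 0.0
                dist[i, j] = dist[j, i] = 1.0 - min(sim, 1.0)
        if failures:
            raise AlignmentError(f"pairwise alignment failures: {failures}")
        guide = hierarchy.linkage(squareform(dist, checks=False),
                                  method="average")

    clusters: dict[int, _Cluster] = {
        i: _Cluster(i, s) for i, s in enumerate(structures)}
    for k, (left, right, _, _) in enumerate(guide):
        clusters[n + k] = _merge_clusters(clusters.pop(int(left)),
                                          clusters.pop(int(right)))
    final = clusters.popitem()[1]
    rows = np.array([final.rows[i] for i in range(n)])
    return StructuralMSA(labels=[s.label for s in structures],
                         sequences=[s.sequence for s in structures],
                         columns=rows)


# ---------------------------------------------------------------------------
# similarity matrices

@dataclass
class SimilarityMatrix:
    """Labelled symmetric matrix with optional hierarchical clustering."""

    labels: list[str]
    values: np.ndarray
    kind: str                                  # identity | rmsd | rmsip | amsm
    linkage: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("matrix must be symmetric")
        want_diag = 0.0 if self.kind == "rmsd" else 1.0
        if not np.allclose(np.diag(v), want_diag, atol=1e-9):
            raise ValueError(f"{self.kind} matrix diagonal must be {want_diag}")
        self.values = v

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def summary(self, include_diagonal: bool = True) -> dict[str, float]:
        """Six-number summary (min, quartiles, mean, max) of the values."""
        if include_diagonal:
            vals = self.values.ravel()
        else:
            iu = np.triu_indices(len(self.labels), k=1)
            vals = self.values[iu]
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        return {"min": float(vals.min()), "q1": float(q1),
                "median": float(med), "mean": float(vals.mean()),
                "q3": float(q3), "max": float(vals.max())}


def sequence_identity_matrix(msa: StructuralMSA) -> SimilarityMatrix:
    """Pairwise identity: identical residues over pairwise alignment length.

    The pairwise alignment length is the number of columns where at least
    one of the two structures is non-gap.
    """
    n = msa.n_structures
    vals = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ri, rj = msa.columns[i], msa.columns[j]
            either = (ri >= 0) | (rj >= 0)
            both = (ri >= 0) & (rj >= 0)
            si = np.array(list(msa.sequences[i]))
            sj = np.array(list(msa.sequences[j]))
            same = np.zeros(msa.n_columns, dtype=bool)
            same[both] = si[ri[both]] == sj[rj[both]]
            length = max(int(either.sum()), 1)
            vals[i, j] = vals[j, i] = same.sum() / length
    return SimilarityMatrix(labels=list(msa.labels), values=vals, kind="identity")


def rmsd_matrix(structures: list[CalphaStructure], msa: StructuralMSA,
                positions: np.ndarray | None = None) -> SimilarityMatrix:
    """Pairwise Kabsch RMSD over selected (fully occupied) MSA columns."""
    if positions is None:
        positions = msa.full_occupancy_columns()
    positions = np.asarray(positions, int)
    if np.any(msa.columns[:, positions] < 0):
        raise ValueError("selected columns contain gaps")
    coords = [s.coords[msa.columns[i, positions]]
              for i, s in enumerate(structures)]
    n = len(structures)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = kabsch_rmsd(coords[i], coords[j])
    return SimilarityMatrix(labels=list(msa.labels), values=vals, kind="rmsd")


def cluster_matrix(m: SimilarityMatrix, method: str = "complete",
                   cut: float | None = None):
    """Attach a hierarchical clustering to a similarity matrix.

    RMSD matrices are clustered directly on their values as distances;
    similarity-kind matrices (identity/rmsip/amsm) on Euclidean distances
    between their rows, matching common clustermap practice.

    Returns ``(matrix, flat_labels)``; flat labels are None without a cut.
    """
    if not np.all(np.isfinite(m.values)):
        i, j = np.argwhere(~np.isfinite(m.values))[0]
        raise ValueError(f"non-finite entry for pair "
                         f"({m.labels[i]}, {m.labels[j]})")
    if m.kind == "rmsd":
        cond = squareform(m.values, checks=False)
    else:
        cond = pdist(m.values, metric="euclidean")
    z = hierarchy.linkage(cond, method=method)
    m.linkage = z
    flat = None
    if cut is not None:
        flat = hierarchy.fcluster(z, t=cut, criterion="distance")
    return m, flat


def cut_k_clusters(m: SimilarityMatrix, k: int) -> np.ndarray:
    """Flat cluster labels at the k-cluster level of the attached tree."""
    if m.linkage is None:
        cluster_matrix(m)
    return hierarchy.fcluster(m.linkage, t=k, criterion="maxclust")


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage tree as a Newick string."""
    tree = hierarchy.to_tree(z)

    def rec(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.get_left(), node.dist)
        right = rec(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"
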