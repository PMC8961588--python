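"""End-to-end comparative analysis: orchestration of every stage.

``run_comparative`` executes the full workflow on a set of Cα structures:
multiple structural alignment, identity and RMSD similarity matrices with
complete-linkage clusterings, iterated-superposition core finding with
inter-helix geometry, ensemble PCA, per-structure elastic-network modes
with fluctuation/deformation profiles, the all-pairs RMSIP clustermap and
per-structure dynamic-domain assignments.  All outputs are plain
machine-readable files (CSV / Newick / FASTA / JSON) plus an in-memory
report dict; a run is fully reproducible from config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import fowlkes_mallows_score

from . import enm as enm_mod
from . import geostas as geo_mod
from .align import (SimilarityMatrix, StructuralMSA, align_coordinates,
                    cluster_matrix, cut_k_clusters, linkage_to_newick,
                    progressive_msa, rmsd_matrix, sequence_identity_matrix)
from .pca import ensemble_pca, loadings_profile, variance_explained
from .structures import (CalphaStructure, ChainSelection, assign_helices,
                         read_pdb_calpha, write_pdb_calpha)
from .superpose import (find_core, fit_ensemble, helix_axis,
                        interhelix_geometry, kabsch_fit)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Declarative description of one comparative run."""

    structures: list[dict] = field(default_factory=list)  # path/chain/label
    alignment_fasta: str | None = None       # imported alignment, else internal
    occupancy_threshold: float = 1.0
    core_threshold: float = 1.0              # Å, pairwise-RMSD stop rule
    core_target_count: int | None = None
    force_field: str = "calpha"
    rmsip_modes: int = 10
    geostas_modes: int = 5
    linkage_method: str = "complete"
    clade_cut: float = 3.0                   # Å, RMSD dendrogram cut
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.occupancy_threshold <= 1.0:
            raise ValueError("occupancy threshold must be in (0, 1]")
        if self.core_threshold <= 0:
            raise ValueError("core threshold must be positive")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def load_structures(config: AnalysisConfig) -> list[CalphaStructure]:
    out = []
    for entry in config.structures:
        sel = ChainSelection(chain_id=entry.get("chain"))
        s = read_pdb_calpha(entry["path"], sel)
        if "label" in entry:
            s.label = entry["label"]
        out.append(assign_helices(s))
    return out


def _occupancy_columns(msa: StructuralMSA, threshold: float) -> np.ndarray:
    return np.nonzero(msa.occupancy >= threshold - 1e-12)[0]


def _write_matrix(m: SimilarityMatrix, outdir: Path | None, stem: str) -> None:
    if outdir is None:
        return
    m.to_dataframe().to_csv(outdir / f"{stem}.csv")
    pd.Series(m.summary()).to_csv(outdir / f"{stem}_summary.csv",
                                  header=["value"])
    if m.linkage is not None:
        (outdir / f"{stem}_tree.nwk").write_text(
            linkage_to_newick(m.linkage, m.labels) + "\n")


def core_helix_geometry(structures, msa, core_columns) -> pd.DataFrame:
    """Angle/distance between the two core-bearing helices, per structure.

    For every structure the two helices containing the most core positions
    are axis-fitted and their acute angle and minimum axis distance
    reported.  Structures whose core maps into fewer than two helices of
    ≥ 5 residues are skipped.
    """
    rows = []
    for i, s in enumerate(structures):
        core_res = msa.columns[i, core_columns]
        core_res = core_res[core_res >= 0]
        counts = []
        for (a, b) in s.helices:
            inside = int(np.sum((core_res >= a) & (core_res < b)))
            if inside and b - a >= 5:
                counts.append((inside, (a, b)))
        counts.sort(reverse=True)
        if len(counts) < 2:
            continue
        (na, ha), (nb, hb) = counts[0], counts[1]
        geom = interhelix_geometry(helix_axis(s.coords[ha[0]:ha[1]]),
                                   helix_axis(s.coords[hb[0]:hb[1]]))
        rows.append({"label": s.label, "helix_a": str(ha), "helix_b": str(hb),
                     "core_in_a": na, "core_in_b": nb,
                     "angle_deg": geom.angle, "distance_A": geom.distance,
                     "centroid_distance_A": geom.centroid_distance})
    return pd.DataFrame(rows)


def run_comparative(config: AnalysisConfig,
                    structures: list[CalphaStructure] | None = None) -> dict:
    """Run the full comparative analysis; returns the report dict.

    ``structures`` may be passed directly (e.g. synthetic ones); otherwise
    they are loaded from the config's file entries.  Per-structure
    failures in the dynamics stages are recorded and skipped, not fatal.
    """
    outdir = Path(config.outdir) if config.outdir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    if structures is None:
        structures = load_structures(config)
    if len(structures) < 2:
        raise ValueError("need at least 2 structures")
    structures = [s if s.helices else assign_helices(s) for s in structures]
    report: dict = {"labels": [s.label for s in structures],
                    "seed": config.seed, "failures": {}}

    # --- alignment ---------------------------------------------------------
    if config.alignment_fasta:
        msa = StructuralMSA.from_fasta(Path(config.alignment_fasta).read_text(),
                                       structures)
        order = [msa.labels.index(s.label) for s in structures]
        msa = StructuralMSA(labels=[msa.labels[i] for i in order],
                            sequences=[msa.sequences[i] for i in order],
                            columns=msa.columns[order])
    else:
        msa = progressive_msa(structures)
    report["msa"] = msa
    report["n_columns"] = msa.n_columns
    cols = _occupancy_columns(msa, config.occupancy_threshold)
    report["n_full_occupancy_columns"] = int(len(
        msa.full_occupancy_columns()))
    report["analysis_columns"] = cols
    if outdir is not None:
        (outdir / "msa.fasta").write_text(msa.to_fasta())

    # --- similarity matrices ----------------------------------------------
    ident = sequence_identity_matrix(msa)
    cluster_matrix(ident, method=config.linkage_method)
    report["identity"] = ident
    _write_matrix(ident, outdir, "identity")

    rmsd = rmsd_matrix(structures, msa, cols)
    _, clades = cluster_matrix(rmsd, method=config.linkage_method,
                               cut=config.clade_cut)
    report["rmsd"] = rmsd
    report["rmsd_clades"] = clades
    _write_matrix(rmsd, outdir, "rmsd")

    # --- superposed ensemble, core, helix geometry -------------------------
    coords = [s.coords[msa.columns[i, cols]] for i, s in enumerate(structures)]
    ensemble = fit_ensemble(coords, labels=[s.label for s in structures],
                            positions=cols)
    core = find_core(ensemble, threshold=config.core_threshold,
                     target_count=config.core_target_count)
    report["ensemble"] = ensemble
    report["core"] = core
    geom = core_helix_geometry(structures, msa, core.retained_positions)
    report["helix_geometry"] = geom
    if outdir is not None:
        core_rows = []
        for c in core.retained_positions:
            row = {"column": int(c)}
            for i, s in enumerate(structures):
                ridx = msa.columns[i, c]
                row[s.label] = s.residue_ids[ridx] if ridx >= 0 else ""
            core_rows.append(row)
        pd.DataFrame(core_rows).to_csv(outdir / "core_residues.csv", index=False)
        geom.to_csv(outdir / "helix_geometry.csv", index=False)
        write_pdb_calpha(
            [CalphaStructure(label=l, residue_ids=list(range(1, len(c) + 1)),
                             sequence="A" * len(c), coords=c)
             for l, c in zip(ensemble.labels, ensemble.coords)],
            outdir / "superposed.pdb")

    # --- PCA ----------------------------------------------------------------
    pca = ensemble_pca(ensemble)
    report["pca"] = pca
    report["variance_fractions"] = {
        k: variance_explained(pca, k) for k in range(1, pca.n_components + 1)}
    if outdir is not None:
        pd.DataFrame({"eigenvalue": pca.eigenvalues,
                      "variance_fraction": pca.eigenvalues / pca.total_variance
                      }).to_csv(outdir / "pca_scree.csv", index=False)
        pd.DataFrame(pca.scores, index=ensemble.labels).to_csv(
            outdir / "pca_scores.csv")
        prof = {f"PC{i+1}": loadings_profile(pca, i)
                for i in range(min(3, pca.n_components))}
        pd.DataFrame(prof, index=cols[:pca.loadings.shape[1]]).to_csv(
            outdir / "pca_loadings.csv")

    # --- per-structure ENM --------------------------------------------------
    ff = enm_mod.ForceField(name=config.force_field)
    mode_sets: dict[str, enm_mod.ModeSet] = {}
    fluct, deform = {}, {}
    for s in structures:
        try:
            modes = enm_mod.normal_modes(enm_mod.build_hessian(s, ff))
            mode_sets[s.label] = modes
            fluct[s.label] = enm_mod.fluctuations(modes, normalize=True)
            deform[s.label] = enm_mod.deformation_energy(modes, s, ff)
        except Exception as exc:   # pragma: no cover - per-structure guard
            logger.error("ENM stage failed for %s: %s", s.label, exc)
            report["failures"][s.label] = f"enm: {exc}"
    report["mode_sets"] = mode_sets
    report["fluctuations"] = fluct
    report["deformation"] = deform
    if outdir is not None:
        for name, prof in (("fluctuations", fluct), ("deformation", deform)):
            rows = [{"label": l, "residue_index": i, name: v}
                    for l, p in prof.items() for i, v in enumerate(p)]
            pd.DataFrame(rows).to_csv(outdir / f"{name}.csv", index=False)

    # --- RMSIP clustermap ---------------------------------------------------
    ok = [s for s in structures if s.label in mode_sets]
    if len(ok) >= 2:
        idx = [i for i, s in enumerate(structures) if s.label in mode_sets]
        sub_msa = StructuralMSA(labels=[structures[i].label for i in idx],
                                sequences=[msa.sequences[i] for i in idx],
                                columns=msa.columns[idx])
        rmsip_m = enm_mod.rmsip_matrix([mode_sets[s.label] for s in ok],
                                       sub_msa, n_modes=config.rmsip_modes,
                                       linkage_method=config.linkage_method)
        report["rmsip"] = rmsip_m
        _write_matrix(rmsip_m, outdir, "rmsip")
        if len(ok) == len(structures) and len(structures) >= 4:
            report["rmsd_vs_rmsip_fowlkes_mallows"] = float(
                fowlkes_mallows_score(cut_k_clusters(rmsd, 2),
                                      cut_k_clusters(rmsip_m, 2)))

    # --- GeoStaS dynamic domains -------------------------------------------
    domains = {}
    for s in structures:
        if s.label not in mode_sets:
            continue
        try:
            frames = geo_mod.mode_ensemble(s, mode_sets[s.label],
                                           n_modes=config.geostas_modes)
            matrix = geo_mod.amsm(frames, source={
                "label": s.label, "n_modes": config.geostas_modes})
            assignment = geo_mod.assign_domains(matrix, k="auto",
                                                seed=config.seed)
            domains[s.label] = (matrix, assignment)
        except Exception as exc:   # pragma: no cover - per-structure guard
            logger.error("GeoStaS stage failed for %s: %s", s.label, exc)
            report["failures"][s.label] = f"geostas: {exc}"
    report["domains"] = domains
    if outdir is not None:
        rows = []
        for label, (matrix, assignment) in domains.items():
            np.savetxt(outdir / f"amsm_{label}.csv", matrix.values,
                       delimiter=",", fmt="%.6f")
            rows += [{"label": label, "residue_index": i, "domain": int(d)}
                     for i, d in enumerate(assignment.labels)]
        pd.DataFrame(rows).to_csv(outdir / "domains.csv", index=False)
        _write_manifest(config, structures, report, outdir)
    return report


def _write_manifest(config, structures, report, outdir: Path) -> None:
    manifest = {
        "seed": config.seed,
        "n_structures": len(structures),
        "structure_hashes": {
            s.label: hashlib.md5(
                np.ascontiguousarray(np.round(s.coords, 3)).tobytes()
            ).hexdigest() for s in structures},
        "n_columns": report["n_columns"],
        "n_full_occupancy_columns": report["n_full_occupancy_columns"],
        "core_size": int(report["core"].n_core),
        "failures": report["failures"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


# ---------------------------------------------------------------------------
# apo / holo comparison

@dataclass
class ApoHoloPair:
    """Ligand-free vs ligand-bound forms with a residue correspondence."""

    apo: CalphaStructure
    holo: CalphaStructure
    correspondence: list[tuple[int, int]]     # (apo index, holo index)

    @classmethod
    def from_structures(cls, apo: CalphaStructure,
                        holo: CalphaStructure) -> "ApoHoloPair":
        """Correspond residues by shared author numbering; fall back to a
        structural alignment when the numbering-based mapping is poor
        (e.g. renumbered constructs)."""
        by_id_holo = {r: i for i, r in enumerate(holo.residue_ids)}
        pairs = [(i, by_id_holo[r]) for i, r in enumerate(apo.residue_ids)
                 if r in by_id_holo]
        same = sum(apo.sequence[i] == holo.sequence[j] for i, j in pairs)
        if len(pairs) < 20 or same < 0.8 * len(pairs):
            aligned, _, _, _ = align_coordinates(apo.coords, holo.coords)
            pairs = aligned
        return cls(apo=apo, holo=holo, correspondence=pairs)


def compare_apo_holo(pair: ApoHoloPair,
                     config: AnalysisConfig | None = None) -> dict:
    """Pairwise apo/holo report: RMSD, dynamics profiles, difference profile."""
    config = config or AnalysisConfig()
    if len(pair.correspondence) < 20:
        raise ValueError("apo/holo correspondence too short (< 20 residues)")
    ia = np.array([p[0] for p in pair.correspondence])
    ih = np.array([p[1] for p in pair.correspondence])
    _, _, rmsd = kabsch_fit(pair.holo.coords[ih], pair.apo.coords[ia])

    ff = enm_mod.ForceField(name=config.force_field)
    out = {"rmsd": rmsd, "n_corresponding": len(ia)}
    for name, s in (("apo", pair.apo), ("holo", pair.holo)):
        modes = enm_mod.normal_modes(enm_mod.build_hessian(s, ff))
        out[f"{name}_fluctuations"] = enm_mod.fluctuations(modes, normalize=True)
        out[f"{name}_deformation"] = enm_mod.deformation_energy(modes, s, ff)
        out[f"{name}_cross_correlation"] = enm_mod.cross_correlation(modes)
    out["fluctuation_difference"] = (out["holo_fluctuations"][ih]
                                     - out["apo_fluctuations"][ia])
    out["deformation_difference"] = (out["holo_deformation"][ih]
                                     - out["apo_deformation"][ia])
    return out
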