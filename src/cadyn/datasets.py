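"""Reference dataset registry: the 20 classical insect OBP crystal structures.

Entry metadata (UniProt accession, organism, common abbreviation, PDB id,
resolution, modelled residue count) for the comparative analysis, plus the
apo/holo pair used in the single-structure comparison.  Coordinate files
are not bundled; ``scripts/fetch_pdb.py`` downloads them from the PDB.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class DatasetEntry:
    uniprot: str
    organism: str
    abbreviation: str
    pdb_id: str
    resolution: float
    n_residues: int
    chain: str | None = None     # None = first chain in the file


#: The 20-structure comparative dataset (X-ray, classical OBPs only).
OBP_DATASET: tuple[DatasetEntry, ...] = (
    DatasetEntry("Q8T6S0", "Anopheles gambiae", "AgamOBP1", "3n7h", 1.60, 125),
    DatasetEntry("Q8T6R7", "Anopheles gambiae", "AgamOBP4", "3q8i", 2.00, 123),
    DatasetEntry("Q7Q9J3", "Anopheles gambiae", "AgamOBP20", "3v2l", 1.80, 120),
    DatasetEntry("Q6Y2R8", "Aedes aegypti", "AaegOBP1", "3k1e", 1.85, 124),
    DatasetEntry("Q1HRL7", "Aedes aegypti", "AaegOBP22", "6oii", 1.85, 120),
    DatasetEntry("Q8T6I2", "Culex quinquefasciatus", "CquiOBP1", "3ogn", 1.30, 124),
    DatasetEntry("O02372", "Drosophila melanogaster", "DmelOBP76a", "2gte", 1.40, 124),
    DatasetEntry("P54195", "Drosophila melanogaster", "DmelOBP28a", "6qq4", 2.00, 121, chain="A"),
    DatasetEntry("W8W3V2", "Ceratitis capitata", "CcapOBP22", "6hhe", 1.52, 116),
    DatasetEntry("P34174", "Bombyx mori", "BmorPBP1", "1dqe", 1.80, 137),
    DatasetEntry("P34170", "Bombyx mori", "BmorGOBP2", "2wc5", 1.90, 141),
    DatasetEntry("D0E9M1", "Amyelois transitella", "AtraPBP1", "4inw", 1.14, 140),
    DatasetEntry("Q8WRW5", "Apis mellifera", "AmelASP1", "3bjh", 1.60, 117),
    DatasetEntry("Q8WRW2", "Apis mellifera", "AmelASP5", "3r72", 1.15, 122),
    DatasetEntry("Q3HM32", "Locusta migratoria", "LmigOBP1", "4pt1", 1.65, 129),
    DatasetEntry("Q8MTC1", "Leucophaea maderae", "LmadPBP1", "1org", 1.70, 118),
    DatasetEntry("A0A0S2E5N6", "Megoura viciae", "MvicOBP3", "4z39", 1.30, 121),
    DatasetEntry("A0A0M4AUH6", "Nasonovia ribisnigri", "NribOBP3", "4z45", 2.02, 118),
    DatasetEntry("L8B8J6", "Phormia regina", "PregOBP56a", "5dic", 1.18, 115),
    DatasetEntry("A0A0R8PDN4", "Chrysopa pallens", "CpalOBP4", "6jpm", 2.10, 119),
)

#: AaegOBP22: open liganded form vs closed ligand-free form (truncated by
#: 4 residues at the carboxy-terminus).
APO_HOLO_PAIR = {"holo": "6oii", "apo": "6og0"}

#: The three homologous mosquito OBPs (sequence identity > 0.8).
MOSQUITO_TRIO = ("3n7h", "3k1e", "3ogn")


def residue_count_summary() -> dict[str, float]:
    """Mean/min/max modelled residue counts of the comparative dataset."""
    counts = [e.n_residues for e in OBP_DATASET]
    return {"n_structures": len(counts),
            "mean": sum(counts) / len(counts),
            "min": min(counts),
            "max": max(counts)}


def entry(pdb_id: str) -> DatasetEntry:
    for e in OBP_DATASET:
        if e.pdb_id == pdb_id:
            return e
    raise KeyError(f"{pdb_id} not in dataset")
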