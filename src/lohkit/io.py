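"""Readers and writers for the pipeline's tabular formats.

All formats are plain text. Genotype cells use the single-letter codes
``M``/``P``/``H``/``-`` on disk and the package codes ``M``/``P``/``HET``/
``MISSING`` in memory. Marker positions are 1-based.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .ddpcr import DdpcrAssay
from .fluctuation import FluctuationExperiment, counts_from_plating
from .phasing import HET, M, MISSING, P, PhasedMarker, PhasedMarkerMap, PhaseVector
from .trait_mapping import ROUGH, SMOOTH, CandidateRegion, CrossMatrix, GeneInterval

__all__ = [
    "read_marker_map",
    "write_marker_map",
    "read_marker_map_vcf",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_cross_matrix",
    "write_cross_matrix",
    "read_fluctuation_csv",
    "read_ddpcr_csv",
    "read_intervals",
    "read_gff3_genes",
    "write_regions",
]

_CELL_TO_CODE = {"M": M, "P": P, "H": HET, "-": MISSING}
_CODE_TO_CELL = {v: k for k, v in _CELL_TO_CODE.items()}

MAP_COLUMNS = ["chrom", "pos", "marker_id", "allele_M", "allele_P"]


def read_marker_map(path: str | Path) -> PhasedMarkerMap:
    """Read a phased marker map TSV (chrom, pos, marker_id, allele_M, allele_P)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(MAP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"marker map missing columns: {sorted(missing)}")
    markers = [
        PhasedMarker(r.chrom, int(r.pos), r.marker_id, r.allele_M, r.allele_P)
        for r in df.itertuples()
    ]
    return PhasedMarkerMap(markers, provenance={"source": str(path)})


def write_marker_map(marker_map: PhasedMarkerMap, path: str | Path) -> None:
    df = pd.DataFrame(
        [(m.chrom, m.pos, m.marker_id, m.allele_M, m.allele_P) for m in marker_map],
        columns=MAP_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_marker_map_vcf(path: str | Path) -> PhasedMarkerMap:
    """Import a phased marker map from a phased-GT VCF.

    Dialect: biallelic SNV/indel records whose first sample carries a phased
    heterozygous genotype; ``0|1`` assigns REF to the M homolog and ALT to
    P, ``1|0`` the reverse. Unphased or homozygous records are skipped.
    Requires cyvcf2 (optional dependency).
    """
    from cyvcf2 import VCF  # optional import; declared under extras

    markers: list[PhasedMarker] = []
    for var in VCF(str(path)):
        if len(var.ALT) != 1:
            continue
        gt = var.genotypes[0]  # [a0, a1, phased]
        if len(gt) < 3 or not gt[2] or gt[0] == gt[1]:
            continue
        ref, alt = var.REF, var.ALT[0]
        allele_m, allele_p = (ref, alt) if gt[0] == 0 else (alt, ref)
        marker_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        markers.append(PhasedMarker(var.CHROM, var.POS, marker_id, allele_m, allele_p))
    return PhasedMarkerMap(markers, provenance={"source": str(path), "format": "vcf"})


def read_genotype_matrix(path: str | Path, ploidy: int = 1) -> dict[str, PhaseVector]:
    """Read a genotype matrix TSV: sample_id column then one column per marker.

    Cells are ``M``/``P``/``H``/``-``; haploid files (``ploidy=1``) reject
    ``H``. Vectors are returned in the file's marker-column order.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "sample_id":
        raise ValueError("genotype matrix must start with a sample_id column")
    vectors: dict[str, PhaseVector] = {}
    for r in df.itertuples(index=False):
        sample_id = r[0]
        calls = []
        for cell in r[1:]:
            cell = "-" if pd.isna(cell) else str(cell)
            if cell not in _CELL_TO_CODE:
                raise ValueError(f"invalid genotype cell {cell!r} for {sample_id}")
            if ploidy == 1 and cell == "H":
                raise ValueError(f"haploid matrix contains H (sample {sample_id})")
            calls.append(_CELL_TO_CODE[cell])
        vectors[sample_id] = PhaseVector(sample_id, calls)
    return vectors


def genotype_matrix_marker_ids(path: str | Path) -> list[str]:
    header = pd.read_csv(path, sep="\t", nrows=0)
    return list(header.columns[1:])


def write_genotype_matrix(
    vectors: dict[str, PhaseVector], marker_ids: list[str], path: str | Path
) -> None:
    rows = []
    for sample_id in sorted(vectors):
        v = vectors[sample_id]
        if len(v.calls) != len(marker_ids):
            raise ValueError(f"vector {sample_id} does not match marker list")
        rows.append([sample_id] + [_CODE_TO_CELL[c] for c in v.calls])
    pd.DataFrame(rows, columns=["sample_id"] + marker_ids).to_csv(path, sep="\t", index=False)


def read_cross_matrix(path: str | Path) -> CrossMatrix:
    """Read a cross-panel CSV: rows MATa ids, columns MATalpha ids, cells R/S/NA."""
    df = pd.read_csv(path, index_col=0, dtype=str)
    mata = [str(i) for i in df.index]
    malpha = [str(c) for c in df.columns]
    cells = {}
    for a in df.index:
        for b in df.columns:
            cell = df.loc[a, b]
            if pd.isna(cell) or cell == "NA":
                continue
            if cell == "R":
                cells[(str(a), str(b))] = ROUGH
            elif cell == "S":
                cells[(str(a), str(b))] = SMOOTH
            else:
                raise ValueError(f"invalid cross cell {cell!r} at ({a}, {b})")
    return CrossMatrix(mata_ids=mata, matalpha_ids=malpha, cells=cells)


def write_cross_matrix(matrix: CrossMatrix, path: str | Path) -> None:
    df = pd.DataFrame("NA", index=matrix.mata_ids, columns=matrix.matalpha_ids)
    for (a, b), pheno in matrix.cells.items():
        df.loc[a, b] = "R" if pheno == ROUGH else "S"
    df.to_csv(path)


FLUCT_COLUMNS = [
    "culture_id",
    "selective_count",
    "selective_dilution",
    "selective_plated_fraction",
    "permissive_count",
    "permissive_dilution",
    "permissive_plated_fraction",
]


def read_fluctuation_csv(path: str | Path, label: str = "") -> FluctuationExperiment:
    """Read a plating table and scale counts to whole-culture (r_i, N_i)."""
    df = pd.read_csv(path)
    missing = set(FLUCT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fluctuation table missing columns: {sorted(missing)}")
    r, n = [], []
    for row in df.itertuples():
        ri, ni = counts_from_plating(
            int(row.selective_count),
            float(row.selective_dilution),
            float(row.selective_plated_fraction),
            int(row.permissive_count),
            float(row.permissive_dilution),
            float(row.permissive_plated_fraction),
        )
        r.append(ri)
        n.append(ni)
    return FluctuationExperiment(r=r, N=n, label=label or str(path))


def read_ddpcr_csv(path: str | Path) -> list[DdpcrAssay]:
    """Read droplet counts: amplicon_id, role, positives, total."""
    df = pd.read_csv(path)
    needed = {"amplicon_id", "role", "positives", "total"}
    if needed - set(df.columns):
        raise ValueError(f"ddPCR table missing columns: {sorted(needed - set(df.columns))}")
    return [
        DdpcrAssay(str(r.amplicon_id), int(r.positives), int(r.total), role=str(r.role))
        for r in df.itertuples()
    ]


def read_intervals(path: str | Path) -> dict[str, list[tuple[float, float]]]:
    """Read endpoint intervals TSV: chrom, left_pos, right_pos (half-open)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[tuple[float, float]]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.chrom), []).append((float(r.left_pos), float(r.right_pos)))
    return out


def read_gff3_genes(path: str | Path) -> list[GeneInterval]:
    """Extract gene intervals from a GFF3 file (type == "gene" rows only)."""
    genes: list[GeneInterval] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("ID") or f"{fields[0]}:{fields[3]}"
            genes.append(GeneInterval(fields[0], int(fields[3]), int(fields[4]), name))
    return genes


def write_regions(regions: list[CandidateRegion], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.chrom, r.start_pos, r.end_pos, r.n_markers,
             "" if r.n_genes is None else r.n_genes, r.orientation)
            for r in regions
        ],
        columns=["chrom", "start", "end", "n_markers", "n_genes", "orientation"],
    )
    df.to_csv(path, sep="\t", index=False)
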