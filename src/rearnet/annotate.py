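"""Nearest-feature annotation of trait-associated SNPs.

Maps each SNP position to the closest feature interval on the same
chromosome ("closest"-style lookup): distance 0 for a SNP inside an
interval, otherwise the gap to the nearer interval edge; equidistant
features are all reported, with the smallest-start one as the primary pick.
The resulting gene lists are exported as plain newline-delimited IDs for
external enrichment tools (DAVID / STRING / KEGG).

Coordinate conventions: BED is 0-based half-open; GFF3 is 1-based closed;
both are normalized to 0-based half-open internally.  SNP positions follow
the 1-based map-file convention and are converted on ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class FeatureInterval:
    """Genomic feature, 0-based half-open internally."""

    chromosome: str
    start: int
    end: int
    feature_id: str
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise ValidationError("empty chromosome name")
        if not self.start < self.end:
            raise ValidationError(
                f"feature {self.feature_id!r}: start {self.start} not < end "
                f"{self.end}"
            )


@dataclass(frozen=True)
class NearestGeneAssignment:
    snp_id: str
    feature_id: str
    distance: int
    tie_ids: tuple[str, ...] = ()


def read_bed(path) -> list[FeatureInterval]:
    """BED with >= 4 columns (chrom, start, end, name[, score, strand])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise ValidationError(f"{path}: BED needs >= 4 columns")
    out = []
    for row in df.itertuples(index=False):
        strand = row[5] if len(row) > 5 else "."
        out.append(
            FeatureInterval(
                chromosome=str(row[0]),
                start=int(row[1]),
                end=int(row[2]),
                feature_id=str(row[3]),
                strand=str(strand),
            )
        )
    return out


def write_bed(features, path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(
                f"{f.chromosome}\t{f.start}\t{f.end}\t{f.feature_id}\t0\t{f.strand}\n"
            )


def _gff3_id(attributes: str) -> str | None:
    for part in attributes.split(";"):
        part = part.strip()
        for key in ("ID=", "gene_id="):
            if part.startswith(key):
                return part[len(key):]
    return None


def read_gff3(path, feature_types=("gene",)) -> list[FeatureInterval]:
    """GFF3 reader; keeps rows of the requested feature types and converts
    1-based closed coordinates to 0-based half-open."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValidationError(
                    f"{path}: line {lineno} has {len(parts)} fields, expected 9"
                )
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            if feature_types and ftype not in feature_types:
                continue
            fid = _gff3_id(attrs)
            if fid is None:
                fid = f"{chrom}:{start}-{end}"
            out.append(
                FeatureInterval(
                    chromosome=chrom,
                    start=int(start) - 1,
                    end=int(end),
                    feature_id=fid,
                    strand=strand,
                )
            )
    return out


def nearest_feature(
    snp: tuple[str, int], features: list[FeatureInterval], snp_id: str = ""
) -> NearestGeneAssignment:
    """Closest feature to a (chromosome, 1-based position) SNP.

    Distance is 0 when the SNP base lies inside the interval, otherwise the
    gap to the nearer edge.  All equidistant features are reported in
    ``tie_ids``; the primary pick is the one with the smallest start.
    """
    chrom, pos1 = snp
    if pos1 < 1:
        raise ValidationError(f"SNP position {pos1} must be 1-based positive")
    pos = pos1 - 1  # 0-based base coordinate
    same = [f for f in features if f.chromosome == chrom]
    if not same:
        raise ValidationError(f"no features on chromosome {chrom!r}")
    starts = np.array([f.start for f in same])
    ends = np.array([f.end for f in same])
    # gap to interval [start, end): 0 if inside
    dist = np.maximum(starts - pos, 0) + np.maximum(pos - (ends - 1), 0)
    dmin = int(dist.min())
    hits = sorted(
        (same[i] for i in np.flatnonzero(dist == dmin)),
        key=lambda f: (f.start, f.feature_id),
    )
    return NearestGeneAssignment(
        snp_id=snp_id or f"{chrom}:{pos1}",
        feature_id=hits[0].feature_id,
        distance=dmin,
        tie_ids=tuple(f.feature_id for f in hits[1:]),
    )


def annotate_snps(
    snp_map: pd.DataFrame, features: list[FeatureInterval], snp_ids=None
) -> list[NearestGeneAssignment]:
    """Nearest-feature assignment for each SNP in (a subset of) a SNP map."""
    wanted = set(snp_ids) if snp_ids is not None else None
    out = []
    for row in snp_map.itertuples(index=False):
        if wanted is not None and row.snp_id not in wanted:
            continue
        out.append(
            nearest_feature(
                (str(row.chromosome), int(row.position)),
                features,
                snp_id=str(row.snp_id),
            )
        )
    return out


def export_gene_list(assignments, path) -> None:
    """Unique feature IDs, one per line, in stable first-seen order."""
    if not assignments:
        raise ValidationError("no assignments to export")
    seen = []
    for a in assignments:
        if a.feature_id not in seen:
            seen.append(a.feature_id)
    with open(path, "w") as fh:
        for fid in seen:
            fh.write(fid + "\n")
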