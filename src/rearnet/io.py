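"""Readers and writers for the pipeline's on-disk formats.

All intermediates are plain text: comma/tab-delimited tables with a header
row for phenotypes and dosages, the 4-column whitespace PLINK ``.map``
dialect (chromosome, snp_id, 0, position) for SNP coordinates, and
two/three-column edge lists for ground truth, blocklists and learned
networks.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .simulate import GenotypeMatrix, GroundTruth

MISSING_CODE = -1


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=True)


def read_phenotypes(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep=None, engine="python", index_col="dam_id")
    return table


def write_genotypes(genotypes: GenotypeMatrix, dosage_path, map_path) -> None:
    df = pd.DataFrame(
        genotypes.dosage,
        index=pd.Index(genotypes.dam_ids, name="dam_id"),
        columns=genotypes.snp_ids,
    )
    df.to_csv(dosage_path)
    write_map(genotypes.snp_map, map_path)


def write_map(snp_map: pd.DataFrame, path) -> None:
    """PLINK .map dialect: chromosome, snp_id, genetic distance 0, position."""
    with open(path, "w") as fh:
        for row in snp_map.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.snp_id}\t0\t{row.position}\n")


def read_map(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ValidationError(
                    f"{path}: line {lineno} has {len(parts)} fields, "
                    "expected 4 (chromosome, snp_id, 0, position)"
                )
            pos = int(parts[3])
            if pos <= 0:
                raise ValidationError(
                    f"{path}: line {lineno} has non-positive position {pos}"
                )
            rows.append((parts[1], parts[0], pos))
    return pd.DataFrame(rows, columns=["snp_id", "chromosome", "position"])


def read_genotypes(
    dosage_path, map_path=None, impute_missing: bool = False
) -> GenotypeMatrix:
    """Read a dosage matrix; ``-1`` marks a missing genotype.

    Missing values abort with a :class:`ValidationError` unless
    ``impute_missing`` is set, in which case each SNP's missing entries are
    replaced by that SNP's modal dosage.
    """
    with open(dosage_path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(dosage_path, sep=sep, index_col=0)
    dosage = df.to_numpy()
    if df.shape[1] == 0:
        dosage = dosage.astype(np.int8).reshape(len(df), 0)
    elif not np.issubdtype(dosage.dtype, np.number):
        raise ValidationError(f"{dosage_path}: non-numeric dosage values")
    missing = dosage == MISSING_CODE
    if missing.any():
        if not impute_missing:
            raise ValidationError(
                f"{dosage_path}: {int(missing.sum())} missing genotypes "
                "(code -1); pass impute_missing=True to impute to the mode"
            )
        for j in np.flatnonzero(missing.any(axis=0)):
            col = dosage[:, j]
            observed = col[col != MISSING_CODE]
            if observed.size == 0:
                raise ValidationError(
                    f"{dosage_path}: SNP column {df.columns[j]} entirely missing"
                )
            mode = np.bincount(observed.astype(int)).argmax()
            col[col == MISSING_CODE] = mode
    bad = ~np.isin(dosage, (0, 1, 2))
    if bad.any():
        raise ValidationError(
            f"{dosage_path}: dosage values outside {{0,1,2}} "
            f"(first offender {dosage[bad][0]!r})"
        )
    if map_path is not None:
        snp_map = read_map(map_path)
        if list(snp_map["snp_id"]) != list(df.columns):
            raise ValidationError(
                f"{map_path}: SNP ids disagree with the dosage matrix columns"
            )
    else:
        snp_map = pd.DataFrame(
            {
                "snp_id": list(df.columns),
                "chromosome": "0",
                "position": np.arange(1, df.shape[1] + 1),
            }
        )
    return GenotypeMatrix(
        dam_ids=[str(i) for i in df.index],
        snp_ids=[str(c) for c in df.columns],
        dosage=dosage.astype(np.int8),
        snp_map=snp_map,
    )


def write_truth(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("parent\tchild\teffect\n")
        for parent, child in truth.dag:
            eff = truth.effect_sizes.get((parent, child), 0.0)
            fh.write(f"{parent}\t{child}\t{eff!r}\n")


def read_truth_edges(path) -> list[tuple[str, str, float]]:
    df = pd.read_csv(path, sep="\t")
    return [
        (str(r.parent), str(r.child), float(r.effect))
        for r in df.itertuples(index=False)
    ]


def write_dataset(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    truth: GroundTruth | None,
    directory,
) -> dict[str, Path]:
    """Write the full synthetic file set; round-trips through the readers."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "phenotypes": directory / "phenotypes.csv",
        "dosage": directory / "dosage.csv",
        "map": directory / "snps.map",
    }
    try:
        write_phenotypes(phenotypes, paths["phenotypes"])
        write_genotypes(genotypes, paths["dosage"], paths["map"])
        if truth is not None:
            paths["truth"] = directory / "truth_edges.tsv"
            write_truth(truth, paths["truth"])
    except OSError as exc:
        raise OSError(f"failed writing dataset under {directory}: {exc}") from exc
    return paths


def write_edge_list(edges, path, header=("from", "to"), extra_columns=None) -> None:
    """Directed edge list with optional extra per-edge columns."""
    extra_columns = extra_columns or {}
    with open(path, "w") as fh:
        fh.write("\t".join(list(header) + list(extra_columns)) + "\n")
        for i, (u, v) in enumerate(edges):
            extras = [str(extra_columns[c][i]) for c in extra_columns]
            fh.write("\t".join([u, v] + extras) + "\n")


def read_edge_list(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
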