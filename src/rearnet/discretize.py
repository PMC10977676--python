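"""Discretization of phenotype and genotype columns for the Bayesian stages.

Both the Naive Bayes pre-selection and the Bayesian-network structure search
operate on discrete variables.  The default trait-to-rule assignment is:

* genetic line and season — fixed categorical codes
  (Line1..Line4 -> 0..3; autumn, spring, summer, winter -> 0..3);
* embryo mortality, first week mortality, natural death — zero-heavy
  percentages, binarized zero/nonzero;
* clutch size — binary split at <= 12 eggs;
* rearing success, flock age, rearing abnormalities — 3-state quantile bins.

SNPs enter as 3-state allele dosage; monomorphic SNPs are dropped and
columns missing a dosage class are compacted to consecutive codes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .simulate import GenotypeMatrix, LINES, SEASONS

logger = logging.getLogger(__name__)

LINE_CODES = {name: i for i, name in enumerate(LINES)}
SEASON_CODES = {name: i for i, name in enumerate(SEASONS)}

#: Default rule per phenotype column; "categorical" needs a mapping,
#: "threshold" a cut point, "quantile" a state count.
DEFAULT_RULES: dict[str, tuple] = {
    "line": ("categorical", LINE_CODES),
    "season": ("categorical", SEASON_CODES),
    "embryo_mortality": ("zero_nonzero",),
    "first_week_mortality": ("zero_nonzero",),
    "natural_death": ("zero_nonzero",),
    "clutch_size": ("threshold", 12),
    "rearing_success": ("quantile", 3),
    "flock_age": ("quantile", 3),
    "rearing_abnormalities": ("quantile", 3),
}

PHENOTYPE_VARS = list(DEFAULT_RULES)


@dataclass
class DiscreteDataset:
    """Jointly discretized phenotype + SNP table.

    ``data`` holds small non-negative integer codes; ``category_maps`` maps
    each variable's code to a human-readable label or interval; ``arity``
    gives the number of states per variable.
    """

    data: pd.DataFrame
    category_maps: dict[str, dict[int, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.data) == 0:
            return
        for col in self.data.columns:
            values = self.data[col].to_numpy()
            states = np.unique(values)
            arity = self.arity[col]
            if values.min() < 0 or values.max() >= arity:
                raise ValidationError(
                    f"column {col!r} has codes outside [0, {arity})"
                )
            if arity < 2:
                raise ValidationError(
                    f"column {col!r} is constant; constant columns cannot "
                    "enter the network"
                )
            cmap = self.category_maps.get(col, {})
            for s in states:
                if int(s) not in cmap:
                    raise ValidationError(
                        f"category map for {col!r} misses observed code {s}"
                    )

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def arity(self) -> dict[str, int]:
        return {
            col: len(self.category_maps.get(col, {}))
            or int(self.data[col].max()) + 1
            for col in self.data.columns
        }

    def arities(self, columns=None) -> np.ndarray:
        cols = columns if columns is not None else self.columns
        a = self.arity
        return np.array([a[c] for c in cols], dtype=np.int64)

    def restrict(self, columns) -> "DiscreteDataset":
        return DiscreteDataset(
            self.data[list(columns)].copy(),
            {c: self.category_maps[c] for c in columns},
        )

    def codes(self, column: str) -> np.ndarray:
        return self.data[column].to_numpy()


def encode_categorical(values, mapping: dict[str, int]) -> np.ndarray:
    """Encode labels with a fixed label->code mapping; unseen labels error."""
    values = pd.Series(values)
    unseen = set(values.unique()) - set(mapping)
    if unseen:
        raise ValidationError(
            f"unmapped label(s) {sorted(map(str, unseen))} for categorical encoding"
        )
    return values.map(mapping).to_numpy(dtype=np.int64)


def binarize_zero_nonzero(values) -> np.ndarray:
    """0 -> 0, any positive value -> 1; negatives and non-finite rejected."""
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("non-finite value in zero/nonzero binarization")
    if np.any(arr < 0):
        raise ValidationError("negative value in zero/nonzero binarization")
    return (arr > 0).astype(np.int64)


def binarize_threshold(values, threshold: int = 12) -> np.ndarray:
    """Counts <= threshold -> 0, counts > threshold -> 1."""
    arr = np.asarray(values)
    if not np.all(np.isfinite(np.asarray(arr, dtype=float))):
        raise ValidationError("non-finite count in threshold binarization")
    if np.any(np.asarray(arr, dtype=float) % 1 != 0):
        raise ValidationError("threshold binarization expects integer counts")
    if np.any(np.asarray(arr, dtype=float) < 0):
        raise ValidationError("negative count in threshold binarization")
    return (np.asarray(arr, dtype=np.int64) > threshold).astype(np.int64)


def quantile_discretize(values, k: int = 3):
    """Cut at the i/k empirical quantiles (i=1..k-1), left-closed bins.

    Duplicate cut points under heavy ties are collapsed, shrinking the arity;
    the shrinkage is logged rather than treated as an error, since zero-heavy
    traits need not admit k equally filled states.
    Returns ``(codes, bin_labels)``.
    """
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("non-finite value in quantile discretization")
    if k < 2:
        raise ValidationError("quantile discretization needs k >= 2")
    if np.unique(arr).size < 2:
        raise ValidationError(
            "quantile discretization needs at least 2 distinct values"
        )
    cuts = np.unique(np.quantile(arr, np.arange(1, k) / k))
    # left-closed bins: a value equal to a cut belongs to the bin above it
    codes = np.searchsorted(cuts, arr, side="right")
    closed = "left"
    if np.unique(codes).size < 2:
        # a cut sits on the data minimum (zero-heavy column); right-closed
        # bins keep the tied mass below the cut instead of collapsing
        codes = np.searchsorted(cuts, arr, side="left")
        closed = "right"
    # compact away any empty bins
    observed = np.unique(codes)
    remap = {int(old): new for new, old in enumerate(observed)}
    codes = np.array([remap[int(c)] for c in codes], dtype=np.int64)
    if len(observed) < k:
        logger.warning(
            "quantile discretization collapsed to %d states (requested %d)",
            len(observed), k,
        )
    edges = [-np.inf, *(float(c) for c in cuts), np.inf]
    labels = {}
    for new, old in enumerate(observed):
        lo, hi = edges[old], edges[old + 1]
        if closed == "left":
            labels[new] = f"[{lo!r}, {hi!r})"
        else:
            labels[new] = f"({lo!r}, {hi!r}]"
    return codes, labels


def encode_genotype(dosage) -> tuple[np.ndarray, dict[int, str]] | None:
    """Identity 3-state dosage coding; compacts missing classes, drops
    monomorphic columns (returns None with a logged warning)."""
    arr = np.asarray(dosage)
    if not np.isin(arr, (0, 1, 2)).all():
        raise ValidationError("dosage values must be in {0, 1, 2}")
    states = np.unique(arr)
    if states.size < 2:
        logger.warning("monomorphic SNP column dropped")
        return None
    remap = {int(s): i for i, s in enumerate(states)}
    codes = np.array([remap[int(v)] for v in arr], dtype=np.int64)
    labels = {i: f"dosage={s}" for i, s in enumerate(states)}
    return codes, labels


def compute_rearing_success(fwm, ra, nd):
    """Rearing success as 100 minus the summed mortality/removal percentages."""
    fwm, ra, nd = (np.asarray(x, dtype=float) for x in (fwm, ra, nd))
    for name, x in (("first_week_mortality", fwm),
                    ("rearing_abnormalities", ra),
                    ("natural_death", nd)):
        if np.any(x < 0) or np.any(x > 100):
            raise ValidationError(f"{name} outside [0, 100]")
    total = fwm + ra + nd
    if np.any(total > 100):
        raise ValidationError(
            "mortality components sum above 100%; inconsistent data"
        )
    return 100.0 - total


def discretize_phenotypes(
    table: pd.DataFrame, rules: dict[str, tuple] | None = None
) -> DiscreteDataset:
    """Apply the per-trait rules to a phenotype table."""
    rules = rules if rules is not None else DEFAULT_RULES
    data = {}
    maps: dict[str, dict[int, str]] = {}
    for col, rule in rules.items():
        if col not in table.columns:
            raise ValidationError(f"phenotype column {col!r} missing from table")
        kind = rule[0]
        if kind == "categorical":
            mapping = rule[1]
            data[col] = encode_categorical(table[col], mapping)
            maps[col] = {code: label for label, code in mapping.items()}
        elif kind == "zero_nonzero":
            data[col] = binarize_zero_nonzero(table[col])
            maps[col] = {0: "zero", 1: "nonzero"}
        elif kind == "threshold":
            thr = rule[1]
            data[col] = binarize_threshold(table[col], threshold=thr)
            maps[col] = {0: f"<={thr}", 1: f">{thr}"}
        elif kind == "quantile":
            codes, labels = quantile_discretize(table[col], k=rule[1])
            data[col] = codes
            maps[col] = labels
        else:
            raise ValidationError(f"unknown discretization rule {kind!r}")
    frame = pd.DataFrame(data, index=table.index)
    return DiscreteDataset(frame, maps)


def discretize_genotypes(genotypes: GenotypeMatrix) -> DiscreteDataset:
    data = {}
    maps = {}
    for j, snp in enumerate(genotypes.snp_ids):
        encoded = encode_genotype(genotypes.dosage[:, j])
        if encoded is None:
            continue
        data[snp], maps[snp] = encoded
    frame = pd.DataFrame(
        data, index=pd.Index(genotypes.dam_ids, name="dam_id")
    )
    return DiscreteDataset(frame, maps)


def join_datasets(*datasets: DiscreteDataset) -> DiscreteDataset:
    """Column-wise join on a shared index."""
    frames = [d.data for d in datasets]
    joined = pd.concat(frames, axis=1, join="inner")
    if joined.columns.duplicated().any():
        raise ValidationError("duplicate column names when joining datasets")
    maps = {}
    for d in datasets:
        maps.update(d.category_maps)
    return DiscreteDataset(joined, maps)


def reapply_category_maps(raw: pd.DataFrame, ds: DiscreteDataset) -> pd.DataFrame:
    """Recode raw phenotype columns using the recorded category maps.

    The recorded labels are machine-reparseable ("zero"/"nonzero",
    "<=T"/">T", "[lo, hi)" with repr-precision bounds, or plain category
    labels), so discretization is idempotent: the reproduced codes match the
    original ones bit-exactly.
    """
    out = {}
    for col in ds.columns:
        if col not in raw.columns:
            continue
        cmap = ds.category_maps[col]
        labels = list(cmap.values())
        values = raw[col]
        if set(labels) == {"zero", "nonzero"}:
            out[col] = binarize_zero_nonzero(values)
        elif all(l.startswith(("<=", ">")) for l in labels):
            thr = int(next(l[2:] for l in labels if l.startswith("<=")))
            out[col] = binarize_threshold(values, threshold=thr)
        elif all(l.startswith(("[", "(")) for l in labels):
            arr = np.asarray(values, dtype=float)
            codes = np.zeros(len(arr), dtype=np.int64)
            for code, label in cmap.items():
                lo, hi = (float(x) for x in label[1:-1].split(", "))
                if label.startswith("["):
                    mask = (arr >= lo) & (arr < hi)
                else:
                    mask = (arr > lo) & (arr <= hi)
                codes[mask] = code
            out[col] = codes
        else:
            out[col] = encode_categorical(
                values, {label: code for code, label in cmap.items()}
            )
    return pd.DataFrame(out, index=raw.index)


def category_maps_to_json(ds: DiscreteDataset) -> dict:
    return {
        col: {str(code): label for code, label in ds.category_maps[col].items()}
        for col in ds.columns
    }
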