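"""Forbidden-edge construction for the network-structure search.

Two sources of blocked links:

* **confounded** — rearing success is an arithmetic function of first week
  mortality, rearing abnormalities and natural death, so links among those
  variables (and between each component and the success total) are known a
  priori and would stop the search from looking further; they are blocked in
  both directions.
* **contingency** — phenotype pairs whose Pearson chi-square test of
  independence yields p >= 0.25 show no evidence of dependency; such links
  are candidates for imbalance artefacts and are excluded (both directions
  by default, since lack of dependency is symmetric).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import chi2_contingency

from .discretize import DiscreteDataset
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Confounded-by-construction pairs around the rearing-success formula.
DEFAULT_CONFOUNDED_PAIRS = (
    ("natural_death", "rearing_abnormalities"),
    ("rearing_abnormalities", "rearing_success"),
    ("first_week_mortality", "rearing_success"),
    ("natural_death", "rearing_success"),
)

DEFAULT_P_THRESHOLD = 0.25


@dataclass
class EdgeBlocklist:
    """Set of forbidden directed edges with per-edge provenance."""

    edges: set[tuple[str, str]] = field(default_factory=set)
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)
    p_values: dict[frozenset, float] = field(default_factory=dict)

    def add(self, u: str, v: str, provenance: str, p_value=None) -> None:
        if u == v:
            raise ValidationError(f"self-loop {u!r} cannot be blocked")
        self.edges.add((u, v))
        self.provenance[(u, v)] = provenance
        if p_value is not None:
            self.p_values[frozenset((u, v))] = float(p_value)

    def blocks(self, u: str, v: str) -> bool:
        return (u, v) in self.edges

    def union(self, other: "EdgeBlocklist") -> "EdgeBlocklist":
        merged = EdgeBlocklist(
            edges=set(self.edges) | set(other.edges),
            provenance={**self.provenance, **other.provenance},
            p_values={**self.p_values, **other.p_values},
        )
        return merged

    def __len__(self) -> int:
        return len(self.edges)


def confounded_blocklist(
    components=DEFAULT_CONFOUNDED_PAIRS, known_vars=None
) -> EdgeBlocklist:
    """Block each confounded pair in both directions."""
    bl = EdgeBlocklist()
    for u, v in components:
        if known_vars is not None:
            for name in (u, v):
                if name not in known_vars:
                    raise ValidationError(
                        f"confounded variable {name!r} not in dataset"
                    )
        bl.add(u, v, "confounded")
        bl.add(v, u, "confounded")
    return bl


def chi_square_independence(col_a, col_b) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on the r x c table.

    No continuity correction.  Structurally empty rows/columns (levels
    absent from the data) are dropped with a warning before testing.
    """
    a = np.asarray(col_a)
    b = np.asarray(col_b)
    if a.shape != b.shape:
        raise ValidationError("columns must have equal length")
    levels_a, ia = np.unique(a, return_inverse=True)
    levels_b, ib = np.unique(b, return_inverse=True)
    if levels_a.size < 2 or levels_b.size < 2:
        raise ValidationError("both columns need at least 2 observed levels")
    table = np.zeros((levels_a.size, levels_b.size), dtype=np.int64)
    np.add.at(table, (ia, ib), 1)
    keep_r = table.sum(axis=1) > 0
    keep_c = table.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        logger.warning("dropping empty contingency level(s) before testing")
        table = table[keep_r][:, keep_c]
    stat, p, dof, _ = chi2_contingency(table, correction=False)
    return float(stat), int(dof), float(p)


def contingency_blocklist(
    data: DiscreteDataset,
    phenotype_vars,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    both_directions: bool = True,
) -> EdgeBlocklist:
    """Block every phenotype pair whose independence test gives p >= threshold."""
    phenotype_vars = list(phenotype_vars)
    if len(phenotype_vars) < 2:
        raise ValidationError("need at least 2 phenotype variables")
    bl = EdgeBlocklist()
    for u, v in combinations(phenotype_vars, 2):
        try:
            _, _, p = chi_square_independence(data.codes(u), data.codes(v))
        except ValidationError as exc:
            logger.warning("skipping pair (%s, %s): %s", u, v, exc)
            continue
        if p >= p_threshold:
            bl.add(u, v, "contingency", p_value=p)
            if both_directions:
                bl.add(v, u, "contingency", p_value=p)
    return bl


def build_blocklist(
    data: DiscreteDataset,
    phenotype_vars,
    confounded_pairs=DEFAULT_CONFOUNDED_PAIRS,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> EdgeBlocklist:
    """Union of the confounded and contingency blocklists."""
    conf = confounded_blocklist(confounded_pairs, known_vars=set(data.columns))
    cont = contingency_blocklist(data, phenotype_vars, p_threshold)
    return conf.union(cont)
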