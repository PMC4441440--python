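"""Distribution summaries and joint binomial likelihood-ratio tests.

Cell-shape (polygon-class) distributions are compared across conditions by
reducing the multinomial response to a trinomial one — hexagons, the second
most common class, and everything else — and fitting two nested binomial
responses: (1) hexagon vs all other shapes, and (2) second-most-common
shape vs all shapes except hexagons.  The two likelihood-ratio (G)
statistics are independent and additive, so the joint test comparing ``n``
conditions has ``2(n - 1)`` degrees of freedom.  This is the fixed-effects
form of the comparison; replicate-level uncertainty is provided by a
bootstrap companion rather than a per-individual random effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .topology import ShapeCensus

__all__ = [
    "TrinomialTable", "LRTestResult", "shape_frequencies",
    "trinomial_reduce", "binomial_g_statistic", "joint_binomial_lr",
    "bootstrap_compare", "synthetic_census", "pool_censuses",
]

HEXAGON_CLASS = 6


def pool_censuses(censuses: list[ShapeCensus]) -> dict[int, int]:
    pooled: dict[int, int] = {}
    for c in censuses:
        for k, v in c.counts.items():
            pooled[k] = pooled.get(k, 0) + v
    return pooled


def shape_frequencies(censuses: ShapeCensus | list[ShapeCensus]
                      ) -> pd.DataFrame:
    """Per-class frequencies (count / total); with >= 2 replicates, the
    standard error of the mean frequency across replicates is included."""
    if isinstance(censuses, ShapeCensus):
        censuses = [censuses]
    if not censuses or all(c.total == 0 for c in censuses):
        raise ValueError("empty census")
    classes = sorted({k for c in censuses for k in c.counts})
    pooled = pool_censuses(censuses)
    total = sum(pooled.values())
    rows = []
    per_rep = np.array([[c.counts.get(k, 0) / c.total for k in classes]
                        for c in censuses if c.total > 0])
    for idx, k in enumerate(classes):
        row = {"polygon_class": k, "count": pooled[k],
               "frequency": pooled[k] / total}
        if per_rep.shape[0] >= 2:
            row["se"] = float(per_rep[:, idx].std(ddof=1) /
                              math.sqrt(per_rep.shape[0]))
        else:
            row["se"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class TrinomialTable:
    """Per-condition (hexagon, second-most-common, remainder) counts.

    The "second most common" class is determined on the data pooled over
    all conditions, so it is identical across conditions within one test.
    """

    conditions: list[str]
    counts: np.ndarray          # shape (n_conditions, 3)
    second_class: int
    tie_logged: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 3:
            raise ValueError("counts must have shape (n_conditions, 3)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")


def trinomial_reduce(censuses_by_condition: dict[str, list[ShapeCensus]]
                     ) -> TrinomialTable:
    """Reduce multinomial censuses to (hexagon, second, rest) counts.

    The second response class is the most common non-hexagon class in the
    pooled data; ties are broken toward the smaller polygon class (logged
    on the returned table).
    """
    if not censuses_by_condition:
        raise ValueError("at least one condition required")
    conditions = list(censuses_by_condition)
    pooled: dict[int, int] = {}
    for cond in conditions:
        cs = censuses_by_condition[cond]
        if isinstance(cs, ShapeCensus):
            cs = [cs]
            censuses_by_condition = {**censuses_by_condition, cond: cs}
        for k, v in pool_censuses(cs).items():
            pooled[k] = pooled.get(k, 0) + v
    non_hex = {k: v for k, v in pooled.items()
               if k != HEXAGON_CLASS and v > 0}
    if pooled.get(HEXAGON_CLASS, 0) == 0:
        raise ValueError("no hexagons in pooled data")
    if not non_hex:
        raise ValueError("pooled data is all hexagons; second response "
                         "class undefined")
    top = max(non_hex.values())
    tied = sorted(k for k, v in non_hex.items() if v == top)
    second = tied[0]
    tie = len(tied) > 1

    rows = []
    for cond in conditions:
        cs = censuses_by_condition[cond]
        if isinstance(cs, ShapeCensus):
            cs = [cs]
        p = pool_censuses(cs)
        hexa = p.get(HEXAGON_CLASS, 0)
        sec = p.get(second, 0)
        rest = sum(v for k, v in p.items()
                   if k not in (HEXAGON_CLASS, second))
        rows.append((hexa, sec, rest))
    return TrinomialTable(conditions, np.array(rows, float), second, tie)


@dataclass
class LRTestResult:
    lr_statistic: float
    df: int
    p_value: float
    components: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"lr": self.lr_statistic, "df": self.df, "p": self.p_value,
                "components": self.components, "warnings": self.warnings}


def binomial_g_statistic(table: np.ndarray) -> tuple[float, int]:
    """G statistic (2 sum O ln(O/E)) of an n x 2 success/failure table
    against the pooled-proportion null; df = n - 1.

    Uses the continuity convention 0 ln 0 = 0.  Rows with zero margin are
    the caller's responsibility.
    """
    t = np.asarray(table, float)
    if t.ndim != 2 or t.shape[1] != 2:
        raise ValueError("expected an n x 2 table")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    total = t.sum()
    if total <= 0:
        raise ValueError("empty table")
    E = np.outer(row, col) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(t > 0, t * np.log(np.where(t > 0, t, 1.0) /
                                           np.where(E > 0, E, 1.0)), 0.0)
    return float(2.0 * terms.sum()), t.shape[0] - 1


def joint_binomial_lr(table: TrinomialTable) -> LRTestResult:
    """Joint binomial likelihood-ratio test over a trinomial table.

    Component 1: hexagons vs all other shapes across conditions.
    Component 2: second class vs remainder, excluding hexagons.
    The component G statistics add; with ``n`` conditions and no degenerate
    margins the combined test has ``2(n - 1)`` df; a condition with a zero
    total in a component is dropped from that component with its df, and
    flagged.
    """
    n = len(table.conditions)
    if n < 2:
        raise ValueError("need >= 2 conditions to compare")
    counts = table.counts
    warnings: list[str] = []
    components: list[dict] = []
    lr_total, df_total = 0.0, 0

    specs = [
        ("hexagon_vs_rest",
         np.column_stack([counts[:, 0], counts[:, 1] + counts[:, 2]])),
        ("second_vs_rest_excl_hexagons",
         np.column_stack([counts[:, 1], counts[:, 2]])),
    ]
    for name, tab in specs:
        keep = tab.sum(axis=1) > 0
        if not keep.all():
            dropped = [table.conditions[q] for q in np.nonzero(~keep)[0]]
            warnings.append(f"{name}: zero-margin condition(s) dropped "
                            f"({', '.join(map(str, dropped))}); df reduced")
        sub = tab[keep]
        if sub.shape[0] < 2:
            warnings.append(f"{name}: fewer than 2 usable conditions; "
                            "component skipped")
            components.append({"name": name, "lr": 0.0, "df": 0})
            continue
        g, df = binomial_g_statistic(sub)
        components.append({"name": name, "lr": g, "df": df})
        lr_total += g
        df_total += df
    if df_total == 0:
        raise ValueError("no usable component in the joint test")
    p = float(sps.chi2.sf(lr_total, df_total))
    return LRTestResult(lr_total, df_total, p, components, warnings)


# ---------------------------------------------------------------------------
# bootstrap companion

def bootstrap_compare(censuses_by_condition: dict[str, list[ShapeCensus]],
                      n_boot: int, rng: np.random.Generator,
                      classes: list[int] | None = None,
                      ci: float = 0.95) -> pd.DataFrame:
    """Replicate-level bootstrap of per-class frequency differences.

    Resamples replicates (with replacement) within each condition and
    reports percentile intervals of the frequency difference of every
    later condition minus the first.  Requires >= 2 replicates per
    condition and ``n_boot`` >= 1.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    conds = list(censuses_by_condition)
    if len(conds) < 2:
        raise ValueError("need >= 2 conditions")
    for cond, cs in censuses_by_condition.items():
        if len(cs) < 2:
            raise ValueError(f"condition {cond!r} needs >= 2 replicates")
    if classes is None:
        classes = sorted({k for cs in censuses_by_condition.values()
                          for c in cs for k in c.counts})

    def freq_matrix(cs: list[ShapeCensus]) -> np.ndarray:
        return np.array([[c.counts.get(k, 0) / c.total for k in classes]
                         for c in cs])

    mats = {cond: freq_matrix(cs) for cond, cs in
            censuses_by_condition.items()}
    alpha = (1.0 - ci) / 2.0
    rows = []
    ref = conds[0]
    diffs = {cond: np.empty((n_boot, len(classes))) for cond in conds[1:]}
    for bidx in range(n_boot):
        means = {}
        for cond in conds:
            m = mats[cond]
            pick = rng.integers(0, m.shape[0], size=m.shape[0])
            means[cond] = m[pick].mean(axis=0)
        for cond in conds[1:]:
            diffs[cond][bidx] = means[cond] - means[ref]
    for cond in conds[1:]:
        lo = np.quantile(diffs[cond], alpha, axis=0)
        hi = np.quantile(diffs[cond], 1.0 - alpha, axis=0)
        point = mats[cond].mean(axis=0) - mats[ref].mean(axis=0)
        for idx, k in enumerate(classes):
            rows.append({"condition": cond, "reference": ref,
                         "polygon_class": k, "difference": point[idx],
                         "ci_low": lo[idx], "ci_high": hi[idx]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic censuses

def synthetic_census(class_probabilities: dict[int, float], n_cells: int,
                     n_replicates: int, rng: np.random.Generator,
                     overdispersion: float = 0.0,
                     condition: str = "synthetic") -> list[ShapeCensus]:
    """Draw replicate censuses from a multinomial shape distribution.

    ``overdispersion`` > 0 adds a between-replicate random effect by
    perturbing the log-probabilities with i.i.d. normal noise of that
    standard deviation and renormalising (a logit-normal random effect,
    emulating per-individual heterogeneity).
    """
    classes = sorted(class_probabilities)
    p = np.array([class_probabilities[k] for k in classes], float)
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("class probabilities must be >= 0 and sum to 1")
    if n_cells < 1 or n_replicates < 1:
        raise ValueError("n_cells and n_replicates must be >= 1")
    out = []
    for rep in range(n_replicates):
        if overdispersion > 0:
            with np.errstate(divide="ignore"):
                logits = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)),
                                  -np.inf)
            logits = logits + rng.normal(0.0, overdispersion, size=p.size)
            q = np.exp(logits - logits.max())
            q[p == 0] = 0.0
            q /= q.sum()
        else:
            q = p
        draw = rng.multinomial(n_cells, q)
        counts = {k: int(v) for k, v in zip(classes, draw) if v > 0}
        out.append(ShapeCensus(counts, condition, str(rep)))
    return out
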