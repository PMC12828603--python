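"""Group-level inference: paired t-tests with Cohen's d and JZS Bayes
factors, Benjamini-Hochberg FDR, and the three contrast batteries run on
subject-level connectivity values (bidirectional asymmetries, stimulation
contrasts, and net bilateral-difference contrasts).

Conventions (validated against printed worked examples): two-tailed p from
Student's t with df = n-1; Cohen's d for the paired design d = |t|/sqrt(n);
BF10 is the default JZS Bayes factor (zero-centered Cauchy prior on the
standardized effect, scale sqrt(2)/2) interpreted on the Lee & Wagenmakers
scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
import pingouin
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "ContrastSpec",
    "paired_test",
    "p_from_t",
    "d_from_t",
    "bayes_factor",
    "evidence_label",
    "fdr_adjust",
    "run_contrast",
]

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    """One paired-test row: t, df, two-tailed p, effect size, BF10."""

    t: float
    df: int
    p: float
    d: float
    bf10: float
    evidence: str
    mean_diff: float
    sem_diff: float
    p_fdr: float = np.nan


def p_from_t(t: float, df: int) -> float:
    """Two-tailed p-value of |t| under Student's t with ``df`` degrees."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(2.0 * sps.t.sf(abs(t), df))


def d_from_t(t: float, n: int) -> float:
    """Cohen's d for a paired design: d = |t| / sqrt(n)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return float(abs(t) / np.sqrt(n))


def bayes_factor(t: float, n: int) -> float:
    """JZS Bayes factor BF10 for a paired / one-sample t statistic.

    Zero-centered Cauchy prior on the standardized effect size with scale
    sqrt(2)/2, evaluated by numerical integration; strictly increasing in
    |t| at fixed n.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    bf = pingouin.bayesfactor_ttest(t, n, paired=True, r=np.sqrt(2) / 2)
    bf = float(bf)
    if not np.isfinite(bf) or bf <= 0:
        raise ArithmeticError(
            f"Bayes factor integration failed for t={t}, n={n} (got {bf})"
        )
    return bf


#: Lee & Wagenmakers evidence bins; boundaries go to the higher-evidence
#: bin, and BF10 = 1 counts as (anecdotal) evidence toward H0.
_H1_BINS = [(100.0, "extreme H1"), (30.0, "very strong H1"),
            (10.0, "strong H1"), (3.0, "moderate H1"), (1.0, "anecdotal H1")]
_H0_BINS = [(1.0 / 100.0, "extreme H0"), (3.0 / 100.0, "very strong H0"),
            (1.0 / 10.0, "strong H0"), (1.0 / 3.0, "moderate H0"),
            (1.0, "anecdotal H0")]


def evidence_label(bf10: float) -> str:
    """Categorical evidence label for a Bayes factor."""
    if not bf10 > 0:
        raise ValueError("bf10 must be > 0")
    if bf10 > 1.0:
        for lo, label in _H1_BINS:
            if bf10 >= lo:
                return label
    for hi, label in _H0_BINS:
        if bf10 <= hi:
            return label
    raise AssertionError("unreachable")


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    _, adj, _, _ = multipletests(p.ravel(), method="fdr_bh")
    return adj.reshape(p.shape)


def paired_test(x, y) -> TestResult:
    """Classical paired t-test of per-subject values ``x`` vs ``y``.

    Returns t, df = n-1, two-tailed p, d = |t|/sqrt(n), the JZS BF10 and
    its evidence label.  FDR adjustment is applied later, across a family.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 paired observations, got {n}")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            # identical inputs: a well-defined null result
            return TestResult(t=0.0, df=n - 1, p=1.0, d=0.0,
                              bf10=bayes_factor(0.0, n),
                              evidence=evidence_label(bayes_factor(0.0, n)),
                              mean_diff=0.0, sem_diff=0.0)
        raise ZeroDivisionError("zero variance of nonzero differences: t undefined")
    t = float(diff.mean() / (sd / np.sqrt(n)))
    bf = bayes_factor(t, n)
    return TestResult(t=t, df=n - 1, p=p_from_t(t, n - 1), d=d_from_t(t, n),
                      bf10=bf, evidence=evidence_label(bf),
                      mean_diff=float(diff.mean()),
                      sem_diff=float(sd / np.sqrt(n)))


@dataclass
class ContrastSpec:
    """Which contrast battery to run on the long-format connectivity table.

    kind:
      * ``asymmetry`` — A->B vs B->A within one condition and phase;
      * ``stimulation`` — sham vs active per directed pair within a phase;
      * ``net_difference`` — per-subject (A->B − B->A) compared between
        conditions within a phase.
    """

    kind: str
    measure: str  # "linear" | "nonlinear"
    phase: str
    condition: str | None = None  # asymmetry only
    conditions: tuple[str, str] = ("sham", "active")  # minuend, subtrahend

    def __post_init__(self) -> None:
        if self.kind not in ("asymmetry", "stimulation", "net_difference"):
            raise ValueError(f"unknown contrast kind {self.kind!r}")
        if self.measure not in ("linear", "nonlinear"):
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.kind == "asymmetry" and self.condition is None:
            raise ValueError("asymmetry contrasts need a condition")


_VALUE_COLS = ["subject", "condition", "phase", "source", "target",
               "measure", "value"]


def _pivot(df: pd.DataFrame, measure: str, phase: str, condition: str,
           source: str, target: str) -> pd.Series:
    sel = df[(df["measure"] == measure) & (df["phase"] == phase)
             & (df["condition"] == condition) & (df["source"] == source)
             & (df["target"] == target)]
    return sel.set_index("subject")["value"]


def run_contrast(values: pd.DataFrame, spec: ContrastSpec,
                 allowed_pairs: set[tuple[str, str]] | None = None,
                 ) -> pd.DataFrame:
    """Run one contrast battery and FDR-correct within it.

    ``values`` is long-format with columns subject, condition, phase,
    source, target, measure, value.  ``allowed_pairs`` optionally
    restricts the directed pairs entering the battery (e.g. only
    connections that exceeded the surrogate null).  Subjects missing
    either side of a pairing are dropped with a log entry.  The returned
    table has one row per contrast with t, d, p, p_fdr, BF10 and label;
    the FDR family is exactly the rows of this battery.
    """
    missing = [c for c in _VALUE_COLS if c not in values.columns]
    if missing:
        raise ValueError(f"values table lacks columns: {missing}")
    rois = sorted(set(values["source"]) | set(values["target"]))
    rows = []
    if spec.kind == "asymmetry":
        for a, b in combinations(rois, 2):
            if allowed_pairs is not None and ((a, b) not in allowed_pairs
                                              and (b, a) not in allowed_pairs):
                continue
            fwd = _pivot(values, spec.measure, spec.phase, spec.condition, a, b)
            rev = _pivot(values, spec.measure, spec.phase, spec.condition, b, a)
            rows.append((f"{a} <> {b}", fwd, rev))
    elif spec.kind == "stimulation":
        c0, c1 = spec.conditions
        for a, b in permutations(rois, 2):
            if allowed_pairs is not None and (a, b) not in allowed_pairs:
                continue
            v0 = _pivot(values, spec.measure, spec.phase, c0, a, b)
            v1 = _pivot(values, spec.measure, spec.phase, c1, a, b)
            rows.append((f"{a} > {b}", v0, v1))
    else:  # net_difference
        c0, c1 = spec.conditions
        for a, b in combinations(rois, 2):
            if allowed_pairs is not None and ((a, b) not in allowed_pairs
                                              and (b, a) not in allowed_pairs):
                continue
            net0 = (_pivot(values, spec.measure, spec.phase, c0, a, b)
                    - _pivot(values, spec.measure, spec.phase, c0, b, a))
            net1 = (_pivot(values, spec.measure, spec.phase, c1, a, b)
                    - _pivot(values, spec.measure, spec.phase, c1, b, a))
            rows.append((f"{a} <> {b} net", net0, net1))
    out = []
    for name, x, y in rows:
        joined = pd.concat({"x": x, "y": y}, axis=1).dropna()
        dropped = max(len(x), len(y)) - len(joined)
        if dropped:
            logger.info("contrast %s: dropped %d incomplete subjects",
                        name, dropped)
        res = paired_test(joined["x"].to_numpy(), joined["y"].to_numpy())
        out.append({
            "connection": name, "kind": spec.kind, "measure": spec.measure,
            "phase": spec.phase, "condition": spec.condition,
            "n": len(joined),
            "mean_a": float(joined["x"].mean()),
            "sem_a": float(joined["x"].sem()),
            "mean_b": float(joined["y"].mean()),
            "sem_b": float(joined["y"].sem()),
            "mean_diff": res.mean_diff, "sem_diff": res.sem_diff,
            "t": res.t, "d": res.d, "p": res.p, "bf10": res.bf10,
            "evidence": res.evidence,
        })
    table = pd.DataFrame(out)
    if len(table):
        table["p_fdr"] = fdr_adjust(table["p"].to_numpy())
        table["significant"] = table["p_fdr"] <= 0.05
    return table
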