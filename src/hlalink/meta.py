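"""Inverse-variance meta-analysis of HLA-A2 carriage odds ratios.

Each case-control study contributes a 2x2 table of antigen carriage
(carrier / non-carrier) against disease status.  Per-study log odds
ratios are pooled by inverse-variance weighting, with the model chosen
by the classical rule: fixed effects when the raw DerSimonian-Laird
between-study variance is non-positive *and* Cochran's Q shows no
heterogeneity at P < 0.10, random effects otherwise.  Publication bias
is probed by leave-one-out sensitivity analysis rather than funnel
regression.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy import stats

__all__ = [
    "StudyRecord",
    "EffectEstimate",
    "PooledResult",
    "SensitivityResult",
    "effect_estimate",
    "pool_fixed",
    "cochran_q",
    "tau_squared",
    "pool",
    "sensitivity",
    "read_study_table",
    "write_study_table",
    "forest_data",
    "write_report",
]

#: 95% two-sided normal quantile used for all confidence intervals (log scale).
CI_MULTIPLIER = 1.96


@dataclass(frozen=True)
class StudyRecord:
    """One study's 2x2 carriage table.

    ``a``/``b`` are carriers/non-carriers among cases, ``c``/``d`` among
    controls.  ``population`` and ``typing_method`` are free-text columns
    used only for subgroup row filters (e.g. Caucasian-only or
    molecular-typing-only analyses).
    """

    label: str
    a: int
    b: int
    c: int
    d: int
    population: str = ""
    typing_method: str = ""

    def __post_init__(self) -> None:
        for cell in ("a", "b", "c", "d"):
            v = getattr(self, cell)
            if v < 0 or v != int(v):
                raise ValueError(f"study {self.label!r}: cell {cell} must be a count >= 0, got {v}")
        if self.a + self.b == 0:
            raise ValueError(f"study {self.label!r}: zero cases")
        if self.c + self.d == 0:
            raise ValueError(f"study {self.label!r}: zero controls")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d


@dataclass(frozen=True)
class EffectEstimate:
    """A study's log odds ratio with its Woolf variance and weight."""

    log_or: float
    variance: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValueError(f"variance must be positive, got {self.variance}")

    @property
    def weight(self) -> float:
        return 1.0 / self.variance


@dataclass(frozen=True)
class PooledResult:
    """Pooled odds ratio with CI, heterogeneity statistics and model choice."""

    model: str  # "fixed" | "random"
    pooled_or: float
    ci_low: float
    ci_high: float
    q: float
    q_p: float
    tau2: float
    k: int

    def __post_init__(self) -> None:
        if self.model not in ("fixed", "random"):
            raise ValueError(f"unknown model {self.model!r}")

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "pooled_or": self.pooled_or,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "q": self.q,
            "q_p": self.q_p,
            "tau2": self.tau2,
            "k": self.k,
        }


@dataclass(frozen=True)
class SensitivityResult:
    excluded_label: str
    result: PooledResult


def effect_estimate(study: StudyRecord, zero_cell_correction: float = 0.5) -> EffectEstimate:
    """Log odds ratio and Woolf variance (1/a + 1/b + 1/c + 1/d) for one study.

    If any cell is zero the Haldane-Anscombe correction is added to all
    four cells of that study (only).  A study whose four cells are all
    zero cannot be corrected into an informative table and is rejected.
    """
    if zero_cell_correction < 0:
        raise ValueError("zero_cell_correction must be >= 0")
    cells = [float(study.a), float(study.b), float(study.c), float(study.d)]
    if min(cells) == 0:
        if max(cells) == 0:
            raise ValueError(f"study {study.label!r}: all four cells are zero")
        if zero_cell_correction == 0:
            raise ValueError(
                f"study {study.label!r}: zero cell with zero_cell_correction=0 gives an undefined log OR"
            )
        cells = [x + zero_cell_correction for x in cells]
    a, b, c, d = cells
    log_or = math.log(a * d / (b * c))
    variance = 1 / a + 1 / b + 1 / c + 1 / d
    return EffectEstimate(log_or=log_or, variance=variance, label=study.label)


def _weighted_mean(estimates: Sequence[EffectEstimate], tau2: float = 0.0) -> tuple[float, float]:
    """Return (pooled log OR, pooled SE) with weights 1/(var_i + tau2)."""
    weights = [1.0 / (e.variance + tau2) for e in estimates]
    wsum = sum(weights)
    mean = sum(w * e.log_or for w, e in zip(weights, estimates)) / wsum
    return mean, wsum ** -0.5


def _result(estimates: Sequence[EffectEstimate], model: str, tau2: float, q: float, q_p: float) -> PooledResult:
    mean, se = _weighted_mean(estimates, tau2 if model == "random" else 0.0)
    return PooledResult(
        model=model,
        pooled_or=math.exp(mean),
        ci_low=math.exp(mean - CI_MULTIPLIER * se),
        ci_high=math.exp(mean + CI_MULTIPLIER * se),
        q=q,
        q_p=q_p,
        tau2=tau2 if model == "random" else 0.0,
        k=len(estimates),
    )


def pool_fixed(estimates: Sequence[EffectEstimate]) -> PooledResult:
    """Fixed-effects (inverse-variance) pooling."""
    estimates = list(estimates)
    if not estimates:
        raise ValueError("cannot pool an empty collection of estimates")
    q, q_p = cochran_q(estimates)
    return _result(estimates, "fixed", 0.0, q, q_p)


def cochran_q(estimates: Sequence[EffectEstimate]) -> tuple[float, float]:
    """Cochran's Q and its upper-tail chi-square P on k-1 df.

    A single study carries no dispersion information: Q = 0 and P = 1
    by convention.
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("cannot compute Q for an empty collection")
    if len(estimates) == 1:
        return 0.0, 1.0
    mean, _ = _weighted_mean(estimates)
    q = sum(e.weight * (e.log_or - mean) ** 2 for e in estimates)
    q_p = float(stats.chi2.sf(q, df=len(estimates) - 1))
    return q, q_p


def tau_squared(estimates: Sequence[EffectEstimate], q: float) -> tuple[float, float]:
    """DerSimonian-Laird between-study variance.

    Returns ``(tau2, tau2_raw)``: the raw moment estimate
    (Q - (k-1)) / (sum(w) - sum(w^2)/sum(w)), which may be negative, and
    the value clipped at zero that is used for pooling.  The raw value
    drives the fixed/random model-selection rule.
    """
    estimates = list(estimates)
    k = len(estimates)
    if k < 2:
        raise ValueError("tau^2 requires at least two studies")
    wsum = sum(e.weight for e in estimates)
    w2sum = sum(e.weight ** 2 for e in estimates)
    denom = wsum - w2sum / wsum
    if denom <= 0:
        raise ValueError("degenerate weights: tau^2 denominator is not positive")
    raw = (q - (k - 1)) / denom
    return max(0.0, raw), raw


def pool(studies: Sequence[StudyRecord], zero_cell_correction: float = 0.5) -> PooledResult:
    """Pool studies with automatic fixed/random model selection.

    Fixed effects are used when the raw DerSimonian-Laird variance is
    <= 0 and Cochran's Q shows no heterogeneity (P >= 0.10); otherwise
    the random-effects model with weights 1/(var_i + tau^2) is used.
    """
    studies = list(studies)
    if not studies:
        raise ValueError("cannot pool an empty collection of studies")
    estimates = [effect_estimate(s, zero_cell_correction) for s in studies]
    if len(estimates) == 1:
        return _result(estimates, "fixed", 0.0, 0.0, 1.0)
    q, q_p = cochran_q(estimates)
    tau2, tau2_raw = tau_squared(estimates, q)
    if tau2_raw <= 0 and q_p >= 0.10:
        return _result(estimates, "fixed", 0.0, q, q_p)
    return _result(estimates, "random", tau2, q, q_p)


def sensitivity(studies: Sequence[StudyRecord], zero_cell_correction: float = 0.5) -> list[SensitivityResult]:
    """Leave-one-out reanalysis; the model is re-selected on each subset."""
    studies = list(studies)
    if len(studies) < 2:
        raise ValueError("sensitivity analysis requires at least two studies")
    out = []
    for i, s in enumerate(studies):
        rest = studies[:i] + studies[i + 1:]
        out.append(SensitivityResult(excluded_label=s.label, result=pool(rest, zero_cell_correction)))
    return out


# ---------------------------------------------------------------------------
# I/O

_COLUMNS = ("label", "population", "typing_method", "cases_pos", "cases_neg", "controls_pos", "controls_neg")


def read_study_table(path: str | Path) -> list[StudyRecord]:
    """Read a tab-separated study table.

    Expected header columns: label, population, typing_method, cases_pos,
    cases_neg, controls_pos, controls_neg.  Lines starting with '#' are
    comments.  Extra columns are ignored.
    """
    path = Path(path)
    records: list[StudyRecord] = []
    header: list[str] | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                missing = [c for c in _COLUMNS if c not in header]
                if missing:
                    raise ValueError(f"{path}:{lineno}: missing columns {missing}")
                continue
            row = dict(zip(header, fields))
            try:
                records.append(
                    StudyRecord(
                        label=row["label"],
                        population=row.get("population", ""),
                        typing_method=row.get("typing_method", ""),
                        a=int(row["cases_pos"]),
                        b=int(row["cases_neg"]),
                        c=int(row["controls_pos"]),
                        d=int(row["controls_neg"]),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: bad study row: {exc}") from exc
    return records


def write_study_table(studies: Iterable[StudyRecord], path: str | Path, header_comment: str = "") -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for s in studies:
            fh.write(f"{s.label}\t{s.population}\t{s.typing_method}\t{s.a}\t{s.b}\t{s.c}\t{s.d}\n")


def forest_data(studies: Sequence[StudyRecord], zero_cell_correction: float = 0.5) -> list[dict]:
    """Per-study OR, 95% CI and relative fixed-effects weight for forest plots."""
    estimates = [effect_estimate(s, zero_cell_correction) for s in studies]
    wsum = sum(e.weight for e in estimates)
    rows = []
    for s, e in zip(studies, estimates):
        se = e.variance ** 0.5
        rows.append(
            {
                "label": s.label,
                "or": math.exp(e.log_or),
                "ci_low": math.exp(e.log_or - CI_MULTIPLIER * se),
                "ci_high": math.exp(e.log_or + CI_MULTIPLIER * se),
                "weight_percent": 100.0 * e.weight / wsum,
            }
        )
    return rows


def write_report(
    result: PooledResult,
    path_prefix: str | Path,
    sensitivity_results: Sequence[SensitivityResult] | None = None,
    forest_rows: Sequence[dict] | None = None,
    params: dict | None = None,
) -> None:
    """Write a pooled-analysis report as TSV + JSON next to ``path_prefix``."""
    prefix = Path(path_prefix)
    with open(f"{prefix}_pooled.tsv", "w") as fh:
        fh.write("model\tpooled_or\tci_low\tci_high\tq\tq_p\ttau2\tk\n")
        r = result
        fh.write(f"{r.model}\t{r.pooled_or:.6g}\t{r.ci_low:.6g}\t{r.ci_high:.6g}\t{r.q:.6g}\t{r.q_p:.6g}\t{r.tau2:.6g}\t{r.k}\n")
    payload: dict = {"pooled": result.to_dict()}
    if params:
        payload["params"] = params
    if sensitivity_results is not None:
        payload["sensitivity"] = [
            {"excluded": s.excluded_label, **s.result.to_dict()} for s in sensitivity_results
        ]
        with open(f"{prefix}_sensitivity.tsv", "w") as fh:
            fh.write("excluded\tmodel\tpooled_or\tci_low\tci_high\tq\tq_p\ttau2\tk\n")
            for s in sensitivity_results:
                r = s.result
                fh.write(
                    f"{s.excluded_label}\t{r.model}\t{r.pooled_or:.6g}\t{r.ci_low:.6g}\t{r.ci_high:.6g}"
                    f"\t{r.q:.6g}\t{r.q_p:.6g}\t{r.tau2:.6g}\t{r.k}\n"
                )
    if forest_rows is not None:
        with open(f"{prefix}_forest.tsv", "w") as fh:
            fh.write("label\tor\tci_low\tci_high\tweight_percent\n")
            for row in forest_rows:
                fh.write(
                    f"{row['label']}\t{row['or']:.6g}\t{row['ci_low']:.6g}\t{row['ci_high']:.6g}\t{row['weight_percent']:.6g}\n"
                )
    with open(f"{prefix}_report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
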