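"""Patient-level aggregation and cohort statistics.

Section scores are averaged to one value per patient and zone (at least
three replicate sections are required, mirroring scoring across three
non-consecutive slides), then summarised per group as mean ± SEM with
classical t-tests: paired between zones of the same patients, pooled-variance
two-sample ("Student's") between patient groups, Welch optional. Raw
two-sided p-values are reported without multiple-testing correction;
significance convention is alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientReplicatesError
from .params import Thresholds
from .scoring import SectionScore

__all__ = [
    "PatientScore",
    "TestResult",
    "aggregate_patient",
    "paired_t",
    "two_sample_t",
    "summarize_cohort",
]

ZONES = ("normal", "transition", "aganglionic")


@dataclass(frozen=True)
class TestResult:
    name: str  # "paired-t" | "two-sample-t" | "welch-t"
    statistic: float
    df: float
    pvalue: float
    n: tuple[int, ...]
    degenerate: bool = False  # zero-variance input

    def to_dict(self) -> dict:
        return {
            "test": self.name,
            "statistic": self.statistic,
            "df": self.df,
            "pvalue": self.pvalue,
            "n": list(self.n),
            "degenerate": self.degenerate,
        }


@dataclass
class PatientScore:
    patient_id: str
    segment: str  # "long" | "short" | other label
    haec: str  # "yes" | "no" | "unknown"
    n_sections: int
    mgr: dict[str, float]  # zone -> mean of per-section MGR
    mgr_totals: dict[str, float]
    composition: dict[str, dict[str, float]]  # zone -> metric means
    ganglia: pd.DataFrame = field(repr=False, default=None)  # pooled per-ganglion table


def aggregate_patient(
    sections: Sequence[SectionScore],
    patient_id: str,
    segment: str = "unknown",
    haec: str = "unknown",
    th: Thresholds | None = None,
) -> PatientScore:
    """Average section scores into one patient record.

    A zone's MGR is present only if at least one section defined it;
    composition metrics are averaged over ganglia pooled across sections.
    """
    th = th or Thresholds()
    if len(sections) < th.n_sections_required:
        raise InsufficientReplicatesError(
            f"patient {patient_id}: {len(sections)} sections, "
            f"{th.n_sections_required} required"
        )
    mgr: dict[str, float] = {}
    mgr_totals: dict[str, float] = {}
    for zone in ZONES:
        vals = [s.mgr[zone] for s in sections if zone in s.mgr]
        if vals:
            mgr[zone] = float(np.mean(vals))
        tvals = [s.mgr_totals[zone] for s in sections if zone in s.mgr_totals]
        if tvals:
            mgr_totals[zone] = float(np.mean(tvals))
    pooled = pd.concat([s.composition_table() for s in sections], ignore_index=True)
    composition: dict[str, dict[str, float]] = {}
    for zone in ZONES:
        sub = pooled[pooled["zone"] == zone]
        if len(sub):
            composition[zone] = {
                "n_ganglia": int(len(sub)),
                "size": float(sub["n_dapi"].mean()),
                "pct_hu": float(sub["pct_hu"].mean()),
                "glia_per_neuron": float(sub["glia_per_neuron"].mean()),
            }
    return PatientScore(
        patient_id=patient_id,
        segment=segment,
        haec=haec,
        n_sections=len(sections),
        mgr=mgr,
        mgr_totals=mgr_totals,
        composition=composition,
        ganglia=pooled,
    )


# --------------------------------------------------------------------------
# t-tests
# --------------------------------------------------------------------------
def paired_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided paired t-test on matched vectors (df = n - 1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired test requires equal-length 1-D vectors")
    n = a.size
    if n < 2:
        raise ValueError("paired test requires n >= 2")
    d = a - b
    if np.var(d, ddof=1) == 0:
        t = 0.0 if d.mean() == 0 else float(np.sign(d.mean()) * np.inf)
        p = 1.0 if d.mean() == 0 else 0.0
        return TestResult("paired-t", t, n - 1, p, (n,), degenerate=True)
    res = stats.ttest_rel(a, b)
    return TestResult("paired-t", float(res.statistic), float(res.df),
                      float(res.pvalue), (n,))


def two_sample_t(
    a: Sequence[float], b: Sequence[float], equal_variance: bool = True
) -> TestResult:
    """Two-sided two-sample t-test; pooled-variance Student by default,
    Welch when ``equal_variance`` is false."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("two-sample test requires n >= 2 per group")
    name = "two-sample-t" if equal_variance else "welch-t"
    if equal_variance and np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        delta = a.mean() - b.mean()
        t = 0.0 if delta == 0 else float(np.sign(delta) * np.inf)
        p = 1.0 if delta == 0 else 0.0
        return TestResult(name, t, a.size + b.size - 2, p,
                          (a.size, b.size), degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=equal_variance)
    return TestResult(name, float(res.statistic), float(res.df),
                      float(res.pvalue), (a.size, b.size))


# --------------------------------------------------------------------------
# cohort tables
# --------------------------------------------------------------------------
def _zone_vector(patients: Sequence[PatientScore], zone: str) -> np.ndarray:
    return np.array([p.mgr[zone] for p in patients if zone in p.mgr])


def _row(
    label: str, patients: Sequence[PatientScore]
) -> tuple[dict, TestResult | None]:
    """NZ/TZ mean ± SEM for one patient group plus the paired NZ-vs-TZ test
    over patients with both zones defined."""
    row: dict = {"group": label, "n": len(patients)}
    for zone, tag in (("normal", "nz"), ("transition", "tz")):
        vals = _zone_vector(patients, zone)
        row[f"{tag}_mean"] = float(vals.mean()) if vals.size else np.nan
        row[f"{tag}_sem"] = (
            float(stats.sem(vals)) if vals.size > 1 else np.nan
        )
        row[f"{tag}_n"] = int(vals.size)
    both = [p for p in patients if "normal" in p.mgr and "transition" in p.mgr]
    test = None
    if len(both) >= 2:
        test = paired_t(
            [p.mgr["normal"] for p in both], [p.mgr["transition"] for p in both]
        )
        row.update(
            test=test.name, statistic=test.statistic, df=test.df,
            pvalue=test.pvalue, test_n=len(both),
        )
    return row, test


def summarize_cohort(
    patients: Sequence[PatientScore],
    grouping: str = "pooled",
    equal_variance: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Cohort summary table.

    ``grouping='pooled'`` gives one all-patients row; ``'segment'`` adds
    long/short rows; ``'haec'`` compares normal-zone MGR and ganglion
    composition between enterocolitis groups with two-sample tests, at both
    the patient and the pooled-ganglion level (labelled accordingly).
    Groups with fewer than two patients get a row without a test.
    """
    if grouping not in ("pooled", "segment", "haec"):
        raise ValueError(f"unknown grouping {grouping!r}")
    rows = []
    tests: dict[str, dict] = {}

    row, test = _row("all", patients)
    rows.append(row)
    if test:
        tests["all_nz_vs_tz"] = test.to_dict()

    if grouping == "segment":
        for seg in sorted({p.segment for p in patients}):
            sub = [p for p in patients if p.segment == seg]
            row, test = _row(seg, sub)
            rows.append(row)
            if test:
                tests[f"{seg}_nz_vs_tz"] = test.to_dict()

    if grouping == "haec":
        groups = {
            "haec": [p for p in patients if p.haec == "yes"],
            "non_haec": [p for p in patients if p.haec == "no"],
        }
        for label, sub in groups.items():
            row, _ = _row(label, sub)
            rows.append(row)
        ga, gb = groups["haec"], groups["non_haec"]
        if len(ga) >= 2 and len(gb) >= 2:
            tests["nz_mgr_haec_vs_non"] = two_sample_t(
                _zone_vector(ga, "normal"), _zone_vector(gb, "normal"),
                equal_variance,
            ).to_dict()
            for metric, col in (
                ("size", "n_dapi"), ("pct_hu", "pct_hu"),
                ("glia_per_neuron", "glia_per_neuron"),
            ):
                by_patient = (
                    [p.composition["normal"][metric] for p in ga
                     if "normal" in p.composition],
                    [p.composition["normal"][metric] for p in gb
                     if "normal" in p.composition],
                )
                if min(map(len, by_patient)) >= 2:
                    tests[f"{metric}_by_patient"] = two_sample_t(
                        *by_patient, equal_variance
                    ).to_dict()
                by_ganglion = tuple(
                    pd.concat([p.ganglia for p in grp], ignore_index=True)
                    .query("zone == 'normal'")[col]
                    .to_numpy()
                    for grp in (ga, gb)
                )
                if min(v.size for v in by_ganglion) >= 2:
                    tests[f"{metric}_by_ganglion"] = two_sample_t(
                        *by_ganglion, equal_variance
                    ).to_dict()
    return pd.DataFrame(rows), tests
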