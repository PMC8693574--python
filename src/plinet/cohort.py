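"""Language-domain scoring and cohort-level statistics.

Raw language test scores are standardized against healthy norms
(z = (raw − mean)/SD), averaged into eight language domains, and a
domain score ≤ −1.5 classifies the subject as language-impaired.

The cohort analyses mirror a four-part design over per-subject network
metrics (10 measures × 2 frequency bands) and domain z-scores:

1. patient vs control group comparison of network metrics
   (Mann–Whitney U per metric × band);
2. rank correlation of metrics with concurrent domain z-scores
   (Kendall tau-b per metric × band × domain, pairwise deletion);
3. impaired vs unimpaired patient comparison (Mann–Whitney U);
4. rank correlation of baseline metrics with follow-up domain
   z-scores (same engine as 2, different outcome timepoint);

plus a descriptive hub-frequency summary: for each electrode, the
percentage of subgroup members whose MST ranks it highest by degree
and/or betweenness (all tied maximizers count).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage import CANONICAL_16
from .mst import MSTResult, top_nodes
from .stats import StatResult, benjamini_hochberg, kendall_tau_b, mann_whitney_u

IMPAIRMENT_THRESHOLD = -1.5

#: network metrics carried per band in a cohort table
METRIC_NAMES = ("pli_mean", "rC", "rL", "SWI",
                "Degr", "Ecc", "BC", "Leaf", "Diam", "TH")
BAND_NAMES = ("theta", "alpha")

#: the eight language domains and their member tests
DEFAULT_DOMAIN_MAP: dict[str, tuple[str, ...]] = {
    "word_retrieval": ("object_naming",),
    "phonology": ("repetition", "letter_fluency"),
    "semantics": ("semantic_odd_picture_out", "category_fluency"),
    "grammar": ("sentence_completion", "action_naming"),
    "comprehension_auditory": ("token_test",),
    "comprehension_visual": ("sentence_judgment",),
    "reading": ("reading",),
    "writing": ("writing",),
}

DOMAIN_NAMES = tuple(DEFAULT_DOMAIN_MAP)


@dataclass
class NormTable:
    """Healthy-population mean and SD per language test."""

    norms: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for test, (mean, sd) in self.norms.items():
            if sd <= 0:
                raise ValueError(f"norm SD must be positive for {test!r}, got {sd}")

    def z(self, test: str, raw: float) -> float:
        if test not in self.norms:
            raise KeyError(f"no norms for test {test!r}")
        mean, sd = self.norms[test]
        return (raw - mean) / sd

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t, m, s) for t, (m, s) in self.norms.items()],
            columns=["test", "mean", "sd"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NormTable":
        return cls({row.test: (row.mean, row.sd) for row in df.itertuples()})


def validate_domain_map(domain_map: dict[str, tuple[str, ...]]) -> None:
    """Every test must belong to exactly one domain."""
    seen: dict[str, str] = {}
    for dom, tests in domain_map.items():
        for t in tests:
            if t in seen:
                raise ValueError(f"test {t!r} in both {seen[t]!r} and {dom!r}")
            seen[t] = dom


@dataclass
class LanguageProfile:
    """Per-subject standardized language scores and impairment status."""

    subject_id: str
    timepoint: str
    test_z: dict[str, float]
    domain_z: dict[str, float]
    impaired: bool
    impaired_domains: list[str] = field(default_factory=list)


def score_language(
    raw_scores: dict[str, float],
    norms: NormTable,
    domain_map: dict[str, tuple[str, ...]] | None = None,
    subject_id: str = "",
    timepoint: str = "T1",
) -> LanguageProfile:
    """Standardize raw test scores and average them into domain scores.

    Tests absent from ``raw_scores`` are simply missing: a domain
    averages its available member tests, and a domain with no
    available test is absent from the profile (never imputed as 0).
    Impairment is a domain score ≤ −1.5 on at least one domain.
    """
    domain_map = DEFAULT_DOMAIN_MAP if domain_map is None else domain_map
    validate_domain_map(domain_map)
    known_tests = {t for tests in domain_map.values() for t in tests}
    unknown = set(raw_scores) - known_tests
    if unknown:
        raise ValueError(f"raw scores for test(s) outside the domain map: "
                         f"{sorted(unknown)}")
    test_z = {t: norms.z(t, raw) for t, raw in raw_scores.items()
              if not (isinstance(raw, float) and np.isnan(raw))}
    domain_z: dict[str, float] = {}
    for dom, tests in domain_map.items():
        avail = [test_z[t] for t in tests if t in test_z]
        if avail:
            domain_z[dom] = float(np.mean(avail))
    impaired_domains = [d for d, z in domain_z.items()
                        if z <= IMPAIRMENT_THRESHOLD]
    return LanguageProfile(subject_id=subject_id, timepoint=timepoint,
                           test_z=test_z, domain_z=domain_z,
                           impaired=bool(impaired_domains),
                           impaired_domains=impaired_domains)


# ---------------------------------------------------------------------------
# Cohort-level analyses (operate on a tidy per-subject DataFrame)
# ---------------------------------------------------------------------------

def metric_columns(metrics=METRIC_NAMES, bands=BAND_NAMES) -> list[str]:
    return [f"{m}_{b}" for b in bands for m in metrics]


def domain_columns(domains=DOMAIN_NAMES) -> list[str]:
    return [f"z_{d}" for d in domains]


def _result_row(band: str, metric: str, res: StatResult, **extra) -> dict:
    row = {"band": band, "metric": metric, "statistic": res.statistic,
           "p": res.p_value, "method": res.method, "sidedness": res.sidedness}
    if res.n is not None:
        row["n"] = res.n
    if res.n1 is not None:
        row.update(n1=res.n1, n2=res.n2)
    row.update(extra)
    return row


def run_group_comparison(
    cohort: pd.DataFrame,
    split_col: str = "group",
    group_a: str = "patient",
    group_b: str = "control",
    metrics=METRIC_NAMES,
    bands=BAND_NAMES,
    adjust: bool = False,
) -> pd.DataFrame:
    """Mann–Whitney U per (metric, band) between two subject groups.

    Returns one row per metric × band with group medians, U and p.
    ``adjust=True`` adds Benjamini–Hochberg adjusted p-values.
    """
    a_rows = cohort[cohort[split_col] == group_a]
    b_rows = cohort[cohort[split_col] == group_b]
    if a_rows.empty or b_rows.empty:
        raise ValueError(
            f"degenerate split: {split_col!r} has empty group "
            f"({group_a!r}: {len(a_rows)}, {group_b!r}: {len(b_rows)})"
        )
    rows = []
    for band in bands:
        for metric in metrics:
            col = f"{metric}_{band}"
            a = a_rows[col].to_numpy(dtype=float)
            b = b_rows[col].to_numpy(dtype=float)
            res = mann_whitney_u(a, b)
            rows.append(_result_row(
                band, metric, res,
                median_a=float(np.nanmedian(a)), median_b=float(np.nanmedian(b)),
                group_a=group_a, group_b=group_b,
            ))
    out = pd.DataFrame(rows)
    if adjust:
        out["adjusted_p"] = benjamini_hochberg(out["p"])
    return out


def run_correlations(
    cohort: pd.DataFrame,
    outcomes: pd.DataFrame | None = None,
    metrics=METRIC_NAMES,
    bands=BAND_NAMES,
    domains=DOMAIN_NAMES,
    sided: str = "two-sided",
    adjust: bool = False,
) -> pd.DataFrame:
    """Kendall tau-b of each network metric with each domain z-score.

    Predictors come from ``cohort`` (e.g. baseline metrics); outcomes
    default to the same table's domain columns but may be a second
    table aligned on ``subject_id`` (e.g. follow-up scores), with
    missing outcomes handled by pairwise deletion.  Cells with fewer
    than 3 complete pairs are reported as not estimable (NaN), never
    dropped from the schema: the output always has one row per
    metric × band × domain.
    """
    if outcomes is None:
        merged = cohort
    else:
        merged = cohort.merge(
            outcomes[["subject_id"] + domain_columns(domains)],
            on="subject_id", suffixes=("_drop", ""), how="inner",
        )
        merged = merged[[c for c in merged.columns if not c.endswith("_drop")]]
    rows = []
    for band in bands:
        for metric in metrics:
            for dom in domains:
                x = merged[f"{metric}_{band}"].to_numpy(dtype=float)
                y = merged[f"z_{dom}"].to_numpy(dtype=float)
                res = kendall_tau_b(x, y, sided=sided)
                rows.append(_result_row(band, metric, res, domain=dom,
                                        estimable=res.estimable))
    out = pd.DataFrame(rows)
    if adjust:
        out["adjusted_p"] = benjamini_hochberg(out["p"])
    return out


def hub_frequency(trees: list[MSTResult], nodes=CANONICAL_16) -> pd.DataFrame:
    """Percentage of subjects ranking each node highest in their MST.

    For each node: the share of subjects whose top-degree set, top-BC
    set, or either ("combined") includes that node.  A subject with k
    tied top nodes increments all k counts, so columns can sum to more
    than 100%.
    """
    if not trees:
        raise ValueError("hub frequency needs a nonempty subgroup")
    n_subj = len(trees)
    counts = {lab: {"degree": 0, "bc": 0, "combined": 0} for lab in nodes}
    for tree in trees:
        by_deg, by_bc = top_nodes(tree)
        for lab in by_deg:
            counts[lab]["degree"] += 1
        for lab in by_bc:
            counts[lab]["bc"] += 1
        for lab in set(by_deg) | set(by_bc):
            counts[lab]["combined"] += 1
    rows = [{"node": lab,
             "pct_top_degree": 100.0 * counts[lab]["degree"] / n_subj,
             "pct_top_bc": 100.0 * counts[lab]["bc"] / n_subj,
             "pct_top_combined": 100.0 * counts[lab]["combined"] / n_subj,
             "n_subjects": n_subj}
            for lab in nodes]
    return pd.DataFrame(rows)
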