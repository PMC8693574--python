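"""Synthetic EEG and cohorts with known ground truth.

Two generators stand in for unavailable patient data:

**Coupled-oscillator EEG** — 16 channels of the 10-20 analysis montage.
Each connected component of the planted coupling graph shares one
band-limited Gaussian-process carrier; every member channel carries a
copy of the carrier's analytic signal rotated by its cumulative phase
lag (PLI is blind to zero-lag coupling, so pair lags must be nonzero
to be visible — and two non-adjacent channels whose cumulative lags
coincide, e.g. the leaves of an equal-lag star, are deliberately
invisible to it, mimicking a volume-conducted common source).
``coupling_strength`` is the fraction of a channel's oscillatory power
drawn from shared carriers; the remainder is an independent private
oscillation in the same band.  Channels outside every planted pair
carry no oscillation at all, so uncoupled pairs share nothing but
noise.  Independent 1/f-shaped Gaussian noise is added per channel.  With strength 1 and no noise a coupled pair is
an exact constant-lag copy, so its downstream PLI is exactly 1.

**Cohorts with planted associations** — per-subject network metrics
and eight language-domain z-scores drawn from a Gaussian copula.  A
target Kendall tau for a (metric, domain) pair is planted by setting
the latent Pearson correlation to ``rho = sin(pi * tau / 2)`` (exact
for the bivariate normal).  After sampling, a single constant is added
to all patients' domain scores so that exactly
``round(impairment_fraction * n_patients)`` patients have at least one
domain ≤ −1.5 — an affine shift, so every planted rank correlation is
untouched.

All randomness flows from the single integer seed in each spec; there
is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (DEFAULT_DOMAIN_MAP, DOMAIN_NAMES, IMPAIRMENT_THRESHOLD,
                     NormTable, metric_columns)
from .io import Recording
from .montage import CANONICAL_16

#: plausible scale (mean, sd) per network metric, used to map latent
#: normals onto metric-like columns
METRIC_SCALES: dict[str, tuple[float, float]] = {
    "pli_mean": (0.15, 0.03), "rC": (1.05, 0.05), "rL": (0.95, 0.05),
    "SWI": (1.10, 0.05), "Degr": (0.30, 0.05), "Ecc": (0.38, 0.03),
    "BC": (0.55, 0.08), "Leaf": (0.45, 0.05), "Diam": (0.47, 0.04),
    "TH": (0.40, 0.04),
}


@dataclass
class CouplingSpec:
    """Planted pairwise phase couplings for one synthetic recording."""

    node_pairs: list[tuple[str, str]] = field(default_factory=list)
    phase_lag: float | list[float] = np.pi / 4
    coupling_strength: float | list[float] = 0.9
    band_center_hz: float = 10.0
    band_width_hz: float = 2.0
    noise_sd: float = 0.5
    seed: int = 0

    def per_pair(self, value) -> list[float]:
        if np.isscalar(value):
            return [float(value)] * len(self.node_pairs)
        if len(value) != len(self.node_pairs):
            raise ValueError("per-pair parameter length mismatch")
        return [float(v) for v in value]

    def validate(self) -> None:
        for a, b in self.node_pairs:
            for lab in (a, b):
                if lab not in CANONICAL_16:
                    raise ValueError(
                        f"unknown channel label {lab!r}; must be one of the "
                        f"16 analysis channels {CANONICAL_16!r}"
                    )
            if a == b:
                raise ValueError(f"self-coupling ({a},{b}) is not allowed")
        for lag in self.per_pair(self.phase_lag):
            if lag == 0:
                raise ValueError(
                    "phase_lag must be nonzero: zero-lag coupling is "
                    "invisible to the phase lag index"
                )
        for s in self.per_pair(self.coupling_strength):
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"coupling_strength must be in [0,1], got {s}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _band_limited_analytic(n: int, fs: float, lo: float, hi: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Complex analytic Gaussian process with power confined to [lo, hi] Hz.

    Real part standardized to unit variance; the imaginary part is its
    exact Hilbert transform (only positive frequencies are populated).
    """
    freqs = np.fft.fftfreq(n, d=1.0 / fs)
    mask = (freqs >= lo) & (freqs <= hi) & (freqs > 0)
    if not mask.any():
        raise ValueError(f"band [{lo}, {hi}] Hz holds no Fourier bin at "
                         f"n={n}, fs={fs}")
    spec = np.zeros(n, dtype=complex)
    k = int(mask.sum())
    spec[mask] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    z = np.fft.ifft(spec)
    sd = z.real.std()
    return z / sd if sd > 0 else z


def _pink_noise(n: int, fs: float, rng: np.random.Generator,
                f_knee: float = 1.0) -> np.ndarray:
    """Unit-variance 1/f-shaped Gaussian noise (flat below ``f_knee``)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, f_knee))
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    return x / x.std()


def _component_phase_offsets(node_pairs, lags, strengths):
    """Per-node phase offsets within each coupled component.

    Returns ``(offsets, strength_of)``: a list of ``{label: offset}``
    dicts, one per connected component of the coupling graph, plus each
    node's coupling strength (the maximum over its pairs).  Offsets are
    propagated from an arbitrary root over a spanning tree; on cyclic
    coupling graphs any extra-edge lag that conflicts with the tree
    assignment is ignored.
    """
    adj: dict[str, list[tuple[str, float]]] = {}
    strength_of: dict[str, float] = {}
    for (a, b), lag, s in zip(node_pairs, lags, strengths):
        adj.setdefault(a, []).append((b, lag))
        adj.setdefault(b, []).append((a, -lag))
        strength_of[a] = max(strength_of.get(a, 0.0), s)
        strength_of[b] = max(strength_of.get(b, 0.0), s)
    seen: set[str] = set()
    components = []
    for root in adj:
        if root in seen:
            continue
        comp = {root: 0.0}
        seen.add(root)
        frontier = [root]
        while frontier:
            nxt = []
            for u in frontier:
                for v, lag in adj[u]:
                    if v not in comp:
                        comp[v] = comp[u] + lag
                        seen.add(v)
                        nxt.append(v)
            frontier = nxt
        components.append(comp)
    return components, strength_of


def generate_coupled_eeg(
    spec: CouplingSpec,
    duration_s: float = 40.96,
    fs: float = 500.0,
    min_samples: int | None = None,
    amplitude_uv: float = 20.0,
) -> Recording:
    """Synthesize a 16-channel recording with planted phase couplings.

    ``duration_s`` defaults to 40.96 s = 5 epochs x 4096 samples at
    500 Hz, the reference epoching.  ``min_samples`` (when given, e.g.
    by the pipeline) enforces a minimum length with an explicit error.
    """
    spec.validate()
    n = int(round(duration_s * fs))
    if min_samples is not None and n < min_samples:
        raise ValueError(
            f"recording of {n} samples ({duration_s} s at {fs} Hz) is too "
            f"short for the requested epoching; need at least {min_samples} "
            f"samples ({min_samples / fs:.2f} s)"
        )
    rng = np.random.default_rng(spec.seed)
    lo = max(spec.band_center_hz - spec.band_width_hz / 2, 1e-6)
    hi = spec.band_center_hz + spec.band_width_hz / 2
    if hi >= fs / 2:
        raise ValueError(f"carrier band reaches {hi} Hz >= Nyquist ({fs / 2} Hz)")

    lags = spec.per_pair(spec.phase_lag)
    strengths = spec.per_pair(spec.coupling_strength)
    osc = np.zeros((len(CANONICAL_16), n))
    index = {lab: i for i, lab in enumerate(CANONICAL_16)}

    # One shared carrier per connected component of the coupling graph;
    # each member channel carries a copy rotated by its cumulative lag
    # (pair (a, b) with lag θ: b lags a by θ, offsets propagated over a
    # spanning tree of the component).  Two channels of one component
    # whose cumulative lags coincide are zero-lag copies — invisible to
    # the PLI by design, exactly like volume-conducted common sources.
    offsets, strength_of = _component_phase_offsets(
        spec.node_pairs, lags, strengths)
    for component in offsets:
        z = _band_limited_analytic(n, fs, lo, hi, rng)
        for lab, phi in component.items():
            s = strength_of[lab]
            osc[index[lab]] += np.sqrt(s) * (z * np.exp(-1j * phi)).real
            # top up to unit oscillatory power with an independent
            # same-band private component
            if s < 1.0:
                osc[index[lab]] += np.sqrt(1.0 - s) * _band_limited_analytic(
                    n, fs, lo, hi, rng).real
    # channels in no pair carry only noise: uncoupled pairs share
    # nothing but noise

    noise = np.zeros_like(osc)
    if spec.noise_sd > 0:
        for i in range(len(CANONICAL_16)):
            noise[i] = spec.noise_sd * _pink_noise(n, fs, rng)

    return Recording(channel_labels=CANONICAL_16, fs=fs,
                     data=amplitude_uv * (osc + noise))


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """A synthetic cohort with planted metric–language associations."""

    n_patients: int = 15
    n_controls: int = 15
    planted_tau: dict[tuple[str, str], float] = field(default_factory=dict)
    impairment_fraction: float = 0.6
    group_shift: dict[str, float] = field(default_factory=dict)
    tumor_type: str = "glioma"
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 3 or self.n_controls < 3:
            raise ValueError("cohort groups need at least 3 subjects each")
        if not 0.0 <= self.impairment_fraction <= 1.0:
            raise ValueError("impairment_fraction must be in [0,1]")
        cols = set(metric_columns())
        for (metric, domain), tau in self.planted_tau.items():
            if metric not in cols:
                raise ValueError(f"unknown metric column {metric!r}")
            if domain not in DOMAIN_NAMES:
                raise ValueError(f"unknown language domain {domain!r}")
            if not -1.0 <= tau <= 1.0:
                raise ValueError(f"planted tau must be in [-1,1], got {tau}")


def _copula_correlation(spec: CohortSpec) -> tuple[np.ndarray, list[str]]:
    """Latent correlation matrix over metric and domain variables."""
    mcols = metric_columns()
    names = mcols + [f"z_{d}" for d in DOMAIN_NAMES]
    k = len(names)
    corr = np.eye(k)
    for (metric, domain), tau in spec.planted_tau.items():
        i = names.index(metric)
        j = names.index(f"z_{domain}")
        rho = np.sin(np.pi * tau / 2.0)
        corr[i, j] = corr[j, i] = rho
    return corr, names


def _sample_gaussian(corr: np.ndarray, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Sample N(0, corr) via eigendecomposition (PSD allowed, e.g. tau=±1)."""
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() < -1e-8:
        raise ValueError(
            "planted tau matrix is infeasible: the implied Gaussian-copula "
            f"correlation matrix is not positive semi-definite "
            f"(min eigenvalue {vals.min():.3g})"
        )
    root = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))
    return rng.standard_normal((n, corr.shape[0])) @ root.T


def _calibrate_impairment(domain_z: np.ndarray, fraction: float) -> float:
    """Constant shift making exactly round(fraction*n) subjects impaired.

    Shifting every domain score by the same constant preserves all
    rank correlations with the metric columns exactly.
    """
    n = domain_z.shape[0]
    k = int(round(fraction * n))
    mins = np.sort(domain_z.min(axis=1))
    thr = IMPAIRMENT_THRESHOLD
    if k == 0:
        return (thr - mins[0]) + 1.0 if mins[0] <= thr else 0.0
    if k == n:
        return thr - mins[-1] if mins[-1] > thr else 0.0
    if mins[k - 1] == mins[k]:
        raise ValueError("tied subject minima; cannot calibrate impairment count")
    return thr - 0.5 * (mins[k - 1] + mins[k])


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Sample a cohort table with planted monotone associations.

    Returns one row per subject at timepoint T1 with columns:
    ``subject_id, group, tumor_type, timepoint``, the 20 network-metric
    columns (10 measures x theta/alpha), the 8 domain z-scores
    (``z_<domain>``) and ``impaired``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    corr, names = _copula_correlation(spec)
    mcols = metric_columns()
    n_m = len(mcols)

    def build(n_subj: int, group: str, planted: bool):
        if planted:
            latent = _sample_gaussian(corr, n_subj, rng)
        else:
            latent = rng.standard_normal((n_subj, len(names)))
        metrics = latent[:, :n_m].copy()
        for j, col in enumerate(mcols):
            mean, sd = METRIC_SCALES[col.rsplit("_", 1)[0]]
            metrics[:, j] = mean + sd * metrics[:, j]
            if group == "control":
                metrics[:, j] -= sd * spec.group_shift.get(col, 0.0)
        domains = latent[:, n_m:].copy()
        return metrics, domains

    pat_metrics, pat_domains = build(spec.n_patients, "patient", planted=True)
    shift = _calibrate_impairment(pat_domains, spec.impairment_fraction)
    pat_domains = pat_domains + shift
    ctl_metrics, ctl_domains = build(spec.n_controls, "control", planted=False)

    rows = []
    for g, metrics, domains, tumor in (
        ("patient", pat_metrics, pat_domains, spec.tumor_type),
        ("control", ctl_metrics, ctl_domains, "none"),
    ):
        for i in range(metrics.shape[0]):
            row = {"subject_id": f"{g[:3]}{i + 1:03d}", "group": g,
                   "tumor_type": tumor, "timepoint": "T1"}
            row.update({c: metrics[i, j] for j, c in enumerate(mcols)})
            row.update({f"z_{d}": domains[i, j]
                        for j, d in enumerate(DOMAIN_NAMES)})
            row["impaired"] = bool(domains[i].min() <= IMPAIRMENT_THRESHOLD)
            rows.append(row)
    return pd.DataFrame(rows)


def generate_followup(
    cohort: pd.DataFrame,
    retention: float = 0.7,
    n_dropout: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Follow-up (T2) language scores for the patients of a cohort.

    Each domain z evolves as ``retention * z_T1 + sqrt(1-retention^2) *
    noise``, keeping (attenuated) monotone associations with the
    baseline metrics.  ``n_dropout`` patients (the last ones) are
    dropped, emulating attrition.  Metric columns are carried over
    unchanged.
    """
    if not 0.0 <= retention <= 1.0:
        raise ValueError("retention must be in [0,1]")
    rng = np.random.default_rng(seed)
    out = cohort[cohort["group"] == "patient"].copy()
    if n_dropout:
        out = out.iloc[: max(len(out) - n_dropout, 0)]
    zcols = [f"z_{d}" for d in DOMAIN_NAMES]
    z = out[zcols].to_numpy(dtype=float)
    noise = rng.standard_normal(z.shape)
    out[zcols] = retention * z + np.sqrt(1.0 - retention ** 2) * noise
    out["timepoint"] = "T2"
    out["impaired"] = (out[zcols].min(axis=1) <= IMPAIRMENT_THRESHOLD)
    return out.reset_index(drop=True)


def generate_norms(test_names: list[str], seed: int = 0) -> NormTable:
    """Plausible healthy-population norms (mean, SD > 0) per test."""
    if not test_names:
        raise ValueError("need at least one test name")
    if len(set(test_names)) != len(test_names):
        dupes = sorted({t for t in test_names if test_names.count(t) > 1})
        raise ValueError(f"duplicate test name(s): {dupes}")
    rng = np.random.default_rng(seed)
    return NormTable({t: (float(rng.uniform(10.0, 60.0)),
                          float(rng.uniform(2.0, 8.0)))
                      for t in test_names})


def raw_scores_from_domains(
    domain_z: dict[str, float],
    norms: NormTable,
    domain_map: dict[str, tuple[str, ...]] | None = None,
) -> dict[str, float]:
    """Raw test scores whose domain averages reproduce given z-scores.

    Every member test of a domain gets that domain's z, mapped back
    through the norms (raw = mean + z * sd) — the inverse of language
    scoring, used to exercise the scoring path end to end.
    """
    domain_map = DEFAULT_DOMAIN_MAP if domain_map is None else domain_map
    raw = {}
    for dom, z in domain_z.items():
        for test in domain_map[dom]:
            mean, sd = norms.norms[test]
            raw[test] = mean + z * sd
    return raw
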