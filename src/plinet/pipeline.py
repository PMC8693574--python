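"""End-to-end orchestration: simulate → preprocess → networks → statistics.

A single :class:`RunConfig` (YAML-serializable, validated before any
computation, unknown keys rejected) and a single integer seed drive a
whole study.  The seed is expanded deterministically into per-stage,
per-subject seeds, so a run is exactly reproducible from its output
directory: every stage writes plain delimited tables, and the resolved
config (seed included) is serialized next to them.

Stages are pure file-in/file-out; inputs are never mutated.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as ch
from . import connectivity as cn
from . import mst as ms
from . import preprocessing as pp
from . import synthetic as sy
from . import weighted as wt
from .io import (Recording, read_recording_edf, read_recording_text,
                 write_matrix, write_recording_edf, write_recording_text)
from .montage import BANDS, CANONICAL_16

log = logging.getLogger("plinet")

CONFIG_VERSION = 1
FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Validated settings for one pipeline run."""

    seed: int = 0
    bands: dict = field(default_factory=lambda: {k: list(v)
                                                 for k, v in BANDS.items()})
    n_epochs: int = pp.DEFAULT_N_EPOCHS
    samples_per_epoch: int = pp.DEFAULT_SAMPLES_PER_EPOCH
    edge_trim_fraction: float = pp.DEFAULT_EDGE_TRIM
    epoch_offsets: list | None = None
    n_surrogates: int = wt.DEFAULT_N_SURROGATES
    montage_exclude: list = field(default_factory=lambda: list(
        ("Cz", "Fp1", "Fp2", "A1", "A2")))
    impairment_threshold: float = ch.IMPAIRMENT_THRESHOLD
    correlation_sided: str = "two-sided"
    adjust_p: bool = False
    include_right_hemisphere: bool = True
    n_patients: int = 15
    n_controls: int = 15
    impairment_fraction: float = 0.6
    followup_retention: float = 0.7
    n_dropout: int = 2
    fs: float = 500.0
    write_edf: bool = False
    config_version: int = CONFIG_VERSION

    def validate(self) -> None:
        if self.config_version != CONFIG_VERSION:
            raise ValueError(f"unsupported config_version {self.config_version}")
        for name, (lo, hi) in self.bands.items():
            if not 0 < lo < hi < self.fs / 2:
                raise ValueError(f"invalid band {name}: ({lo}, {hi}) Hz")
        if self.n_epochs < 1 or self.samples_per_epoch < 2:
            raise ValueError("invalid epoching")
        if not 0 <= self.edge_trim_fraction < 0.5:
            raise ValueError("edge_trim_fraction must be in [0, 0.5)")
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")
        if self.correlation_sided not in ("two-sided", "greater", "less"):
            raise ValueError(f"bad sidedness {self.correlation_sided!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def subject_seed(self, stage: str, index: int) -> int:
        """Deterministic derived seed, kept below 2**31.

        Uses CRC32 of the stage name (not ``hash``, which is salted per
        process) so reruns are reproducible across interpreter sessions.
        """
        import zlib

        h = np.random.SeedSequence(
            [self.seed, zlib.crc32(stage.encode()) % (2 ** 31), index])
        return int(h.generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# Per-subject analysis
# ---------------------------------------------------------------------------

def analyze_recording(rec: Recording, config: RunConfig):
    """All network metrics for one recording, epoch-averaged per band.

    Returns ``(metrics, hub_summaries, mean_matrices)`` where
    ``metrics`` maps ``<metric>_<band>`` to the across-epoch mean,
    ``hub_summaries`` maps band name to an :class:`plinet.mst.MSTResult`
    carrying the across-epoch *average* per-node degree fraction and
    betweenness (used only for hub ranking), and ``mean_matrices`` maps
    band name to the diagnostic entry-wise epoch-mean PLI matrix.
    """
    rec16 = pp.select_montage(rec, exclude=config.montage_exclude)
    rec16 = pp.rereference_average(rec16)
    epochs = pp.segment_epochs(rec16, n_epochs=config.n_epochs,
                               samples_per_epoch=config.samples_per_epoch,
                               offsets=config.epoch_offsets)
    metrics: dict[str, float] = {}
    hubs: dict[str, ms.MSTResult] = {}
    mean_mats: dict[str, cn.ConnectivityMatrix] = {}
    for b_i, (band_name, (lo, hi)) in enumerate(sorted(config.bands.items())):
        ph = pp.bandpass_phase(epochs, (lo, hi),
                               edge_trim=config.edge_trim_fraction)
        cms = cn.pli_matrices(ph)
        per_epoch = []
        deg_acc = {lab: 0.0 for lab in rec16.channel_labels}
        bc_acc = {lab: 0.0 for lab in rec16.channel_labels}
        for e_i, cm in enumerate(cms):
            wm = wt.compute_weighted_metrics(
                cm, n_surrogates=config.n_surrogates,
                seed=config.subject_seed(f"surr-{band_name}", e_i))
            tree = ms.mst_from_matrix(cm)
            vals = wm.as_dict()
            vals.update(tree.as_dict())
            per_epoch.append(vals)
            for lab in rec16.channel_labels:
                deg_acc[lab] += tree.degree_fraction[lab] / len(cms)
                bc_acc[lab] += tree.bc_node[lab] / len(cms)
        metrics.update({f"{k}_{band_name}": v
                        for k, v in cn.aggregate_epochs(per_epoch).items()})
        hubs[band_name] = ms.MSTResult(
            channel_labels=rec16.channel_labels, edges=[],
            degree_fraction=deg_acc, bc_node=bc_acc)
        mean_mats[band_name] = cn.mean_matrix(cms)
    return metrics, hubs, mean_mats


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def cmd_simulate(config: RunConfig, outdir: str | Path) -> Path:
    """Write synthetic recordings, cohort, raw-score and norm tables."""
    outdir = Path(outdir)
    (outdir / "recordings").mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    cohort_spec = sy.CohortSpec(
        n_patients=config.n_patients, n_controls=config.n_controls,
        planted_tau={("Diam_theta", "word_retrieval"): 0.6,
                     ("SWI_alpha", "comprehension_visual"): -0.5},
        impairment_fraction=config.impairment_fraction,
        seed=config.subject_seed("cohort", 0))
    cohort = sy.generate_cohort(cohort_spec)
    followup = sy.generate_followup(
        cohort, retention=config.followup_retention,
        n_dropout=config.n_dropout, seed=config.subject_seed("followup", 0))
    lang = pd.concat([cohort, followup], ignore_index=True)
    lang.to_csv(outdir / "cohort.csv", index=False, float_format=FLOAT_FMT)

    tests = [t for ts in ch.DEFAULT_DOMAIN_MAP.values() for t in ts]
    norms = sy.generate_norms(tests, seed=config.subject_seed("norms", 0))
    norms.to_frame().to_csv(outdir / "norms.csv", index=False,
                            float_format=FLOAT_FMT)
    raw_rows = []
    for row in lang.itertuples():
        domain_z = {d: getattr(row, f"z_{d}") for d in ch.DOMAIN_NAMES}
        raw = sy.raw_scores_from_domains(domain_z, norms)
        raw_rows.append({"subject_id": row.subject_id,
                         "timepoint": row.timepoint, **raw})
    pd.DataFrame(raw_rows).to_csv(outdir / "raw_scores.csv", index=False,
                                  float_format=FLOAT_FMT)

    # per-subject EEG: a few random planted couplings, slightly more and
    # stronger coupling in patients (theta-range carriers) than controls
    # (alpha-range), echoing pathological slow-rhythm synchrony
    manifest = []
    subjects = cohort[["subject_id", "group"]].drop_duplicates()
    for i, row in enumerate(subjects.itertuples()):
        sub_seed = config.subject_seed("eeg", i)
        rng = np.random.default_rng(sub_seed)
        is_patient = row.group == "patient"
        n_pairs = int(rng.integers(2, 5)) if is_patient else int(rng.integers(1, 4))
        pool = list(CANONICAL_16)
        rng.shuffle(pool)
        pairs = [(pool[2 * k], pool[2 * k + 1]) for k in range(n_pairs)]
        spec = sy.CouplingSpec(
            node_pairs=pairs,
            phase_lag=[float(rng.uniform(0.3, np.pi - 0.3)) for _ in pairs],
            coupling_strength=[float(rng.uniform(0.5, 0.9)) for _ in pairs],
            band_center_hz=6.0 if is_patient else 10.0,
            band_width_hz=2.0, noise_sd=0.5, seed=sub_seed)
        rec = sy.generate_coupled_eeg(
            spec, duration_s=config.n_epochs * config.samples_per_epoch
            / config.fs, fs=config.fs,
            min_samples=config.n_epochs * config.samples_per_epoch)
        path = outdir / "recordings" / f"{row.subject_id}.tsv"
        write_recording_text(rec, path)
        if config.write_edf:
            write_recording_edf(rec, path.with_suffix(".edf"))
        manifest.append({"subject_id": row.subject_id, "group": row.group,
                         "timepoint": "T1", "path": str(path.name)})
        log.info("simulated %s (%d planted pairs)", row.subject_id, n_pairs)
    pd.DataFrame(manifest).to_csv(outdir / "manifest.csv", index=False)
    return outdir


def cmd_analyze(config: RunConfig, datadir: str | Path,
                outdir: str | Path | None = None) -> tuple[Path, int]:
    """Compute per-subject network metrics for every manifest entry.

    Returns ``(outdir, n_failed)``; failed subjects are logged and
    skipped, never silently dropped.
    """
    datadir = Path(datadir)
    outdir = Path(outdir) if outdir else datadir
    (outdir / "matrices").mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(datadir / "manifest.csv")
    metric_rows, hub_rows = [], []
    n_failed = 0
    for row in manifest.itertuples():
        path = datadir / "recordings" / row.path
        try:
            if path.suffix.lower() == ".edf":
                rec = read_recording_edf(path)
            else:
                rec = read_recording_text(path)
            metrics, hubs, mean_mats = analyze_recording(rec, config)
        except Exception as exc:  # noqa: BLE001 - per-subject isolation
            log.error("subject %s failed: %s", row.subject_id, exc)
            n_failed += 1
            continue
        metric_rows.append({"subject_id": row.subject_id, "group": row.group,
                            **metrics})
        for band, tree in hubs.items():
            by_deg, by_bc = ms.top_nodes(tree)
            hub_rows.append({"subject_id": row.subject_id, "band": band,
                             "top_degree": ";".join(by_deg),
                             "top_bc": ";".join(by_bc)})
            write_matrix(mean_mats[band].values, mean_mats[band].channel_labels,
                         outdir / "matrices" / f"{row.subject_id}_{band}_mean.tsv")
    pd.DataFrame(metric_rows).to_csv(outdir / "metrics.csv", index=False,
                                     float_format=FLOAT_FMT)
    pd.DataFrame(hub_rows).to_csv(outdir / "hubs.csv", index=False)
    if n_failed:
        log.warning("%d subject(s) failed analysis", n_failed)
    return outdir, n_failed


def _language_from_scores(datadir: Path, timepoint: str) -> pd.DataFrame:
    """Score raw tests against the norms into domain z columns."""
    raw = pd.read_csv(datadir / "raw_scores.csv")
    norms = ch.NormTable.from_frame(pd.read_csv(datadir / "norms.csv"))
    rows = []
    for r in raw[raw["timepoint"] == timepoint].itertuples():
        scores = {t: getattr(r, t) for t in raw.columns
                  if t not in ("subject_id", "timepoint")}
        prof = ch.score_language(scores, norms, subject_id=r.subject_id,
                                 timepoint=timepoint)
        row = {"subject_id": prof.subject_id, "impaired": prof.impaired}
        row.update({f"z_{d}": prof.domain_z.get(d, np.nan)
                    for d in ch.DOMAIN_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)


def cmd_stats(config: RunConfig, datadir: str | Path,
              outdir: str | Path | None = None) -> Path:
    """Run the four cohort analyses plus the hub-frequency summary."""
    datadir = Path(datadir)
    outdir = Path(outdir) if outdir else datadir
    outdir.mkdir(parents=True, exist_ok=True)
    metrics = pd.read_csv(datadir / "metrics.csv")
    lang_t1 = _language_from_scores(datadir, "T1")
    lang_t2 = _language_from_scores(datadir, "T2")
    zcols = [f"z_{d}" for d in ch.DOMAIN_NAMES]
    t1 = metrics.merge(lang_t1, on="subject_id", how="left")

    # (1) patients vs controls on every metric x band
    a1 = ch.run_group_comparison(t1, adjust=config.adjust_p)
    a1.to_csv(outdir / "analysis1_patients_vs_controls.csv", index=False,
              float_format=FLOAT_FMT)

    patients = t1[t1["group"] == "patient"]
    # (2) baseline metrics vs baseline language
    a2 = ch.run_correlations(patients, sided=config.correlation_sided,
                             adjust=config.adjust_p)
    a2.to_csv(outdir / "analysis2_t1_correlations.csv", index=False,
              float_format=FLOAT_FMT)

    # (3) impaired vs unimpaired patients
    pat = patients.copy()
    pat["impairment"] = np.where(pat["impaired"].astype(bool),
                                 "impaired", "unimpaired")
    if pat["impairment"].nunique() == 2:
        a3 = ch.run_group_comparison(pat, split_col="impairment",
                                     group_a="impaired", group_b="unimpaired",
                                     adjust=config.adjust_p)
    else:
        log.warning("impairment split degenerate; emitting empty analysis 3")
        a3 = pd.DataFrame(columns=["band", "metric", "statistic", "p"])
    a3.to_csv(outdir / "analysis3_impaired_vs_not.csv", index=False,
              float_format=FLOAT_FMT)

    # (4) baseline metrics vs follow-up language
    if not lang_t2.empty:
        a4 = ch.run_correlations(patients, outcomes=lang_t2[
            ["subject_id"] + zcols], sided=config.correlation_sided,
            adjust=config.adjust_p)
    else:
        log.warning("no follow-up language scores; emitting empty analysis 4")
        a4 = pd.DataFrame(columns=["band", "metric", "domain", "statistic", "p"])
    a4.to_csv(outdir / "analysis4_t2_correlations.csv", index=False,
              float_format=FLOAT_FMT)

    # (5) hub frequency among impaired patients, per band
    hubs = pd.read_csv(datadir / "hubs.csv")
    impaired_ids = set(lang_t1[lang_t1["impaired"].astype(bool)]["subject_id"])
    impaired_ids &= set(patients["subject_id"])
    hub_tables = []
    for band in sorted(config.bands):
        sub = hubs[(hubs["band"] == band)
                   & hubs["subject_id"].isin(impaired_ids)]
        if sub.empty:
            log.warning("no impaired patients for hub analysis (%s band)", band)
            continue
        trees = []
        for r in sub.itertuples():
            deg = {lab: 0.0 for lab in CANONICAL_16}
            bc = {lab: 0.0 for lab in CANONICAL_16}
            for lab in str(r.top_degree).split(";"):
                deg[lab] = 1.0
            for lab in str(r.top_bc).split(";"):
                bc[lab] = 1.0
            trees.append(ms.MSTResult(channel_labels=CANONICAL_16, edges=[],
                                      degree_fraction=deg, bc_node=bc))
        tab = ch.hub_frequency(trees)
        tab.insert(0, "band", band)
        hub_tables.append(tab)
    hub_out = (pd.concat(hub_tables, ignore_index=True) if hub_tables
               else pd.DataFrame(columns=["band", "node", "pct_top_degree",
                                          "pct_top_bc", "pct_top_combined"]))
    hub_out.to_csv(outdir / "hub_frequency.csv", index=False,
                   float_format=FLOAT_FMT)
    return outdir


def run_all(config: RunConfig, outdir: str | Path) -> Path:
    """simulate → analyze → stats, all into one output directory."""
    config.validate()
    outdir = Path(outdir)
    cmd_simulate(config, outdir)
    _, n_failed = cmd_analyze(config, outdir)
    cmd_stats(config, outdir)
    if n_failed:
        raise RuntimeError(f"{n_failed} subject(s) failed during analysis")
    return outdir
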