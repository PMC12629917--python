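"""End-to-end seeded analysis run: simulate (or load) a cohort, estimate
instantaneous frequency, spectra and bursts per subject, run the group
cluster-permutation contrasts and the time-resolved decoding, and write a
reproducible report.

Re-running with an identical configuration and seed reproduces the report
byte-for-byte: every stage draws its randomness from seeds spawned from the
master seed, and no wall-clock information enters the report files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

import scipy

from ._version import __version__
from .core import BandSpec, EpochSet, NeighborGraph, ValidationError
from .bursts import burst_contrasts, detect_spectral_events, morlet_tfr, summarize_bursts
from .decoding import decode_cohort, time_resolved_decode
from .instafreq import instantaneous_frequency, subject_condition_if
from .io import write_epochs, write_neighbor_graph
from .spectral import irasa_decompose, multitaper_psd, power_contrast
from .stats import Cluster, StatsParams, cluster_permutation_test
from .synth import SimConfig, default_neighbor_graph, simulate_cohort

__all__ = ["RunConfig", "PipelineError", "run_analysis", "summarize_effect",
           "if_contrast_cohort"]

log = logging.getLogger("oscishift")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name, subject, and cause."""

    def __init__(self, stage: str, subject: str | None, cause: BaseException):
        self.stage, self.subject = stage, subject
        msg = f"stage {stage!r}"
        if subject:
            msg += f" (subject {subject})"
        msg += f" failed: {cause}"
        super().__init__(msg)


_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable, versioned).

    Unknown keys in the YAML are errors: silent misconfiguration is the main
    failure mode of analysis pipelines.
    """

    seed: int = 0
    out_dir: str = "run"
    n_subjects: int = 24
    band: tuple = (13.0, 35.0)
    correct_only: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    stats: StatsParams = field(default_factory=lambda: StatsParams(n_permutations=1000))
    burst_fom_threshold: float = 6.0
    burst_channel: str | None = None  # default: first effect channel
    decode_folds: int = 8
    decode_repeats: int = 2
    decode_decimate: int = 8
    schema: int = _SCHEMA_VERSION
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.schema != _SCHEMA_VERSION:
            raise ValidationError(f"RunConfig: unsupported schema {self.schema}")
        if len(self.band) != 2:
            raise ValidationError("RunConfig: band must be (f_lo, f_hi)")

    @property
    def band_spec(self) -> BandSpec:
        return BandSpec(*self.band)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        for k in ("effect_channels", "channel_ids", "condition_names"):
            d["sim"][k] = list(d["sim"][k])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"RunConfig: unknown keys {sorted(unknown)}")
        if "sim" in d:
            sim_known = {f.name for f in dataclasses.fields(SimConfig)}
            sim_unknown = set(d["sim"]) - sim_known
            if sim_unknown:
                raise ValidationError(f"RunConfig: unknown sim keys {sorted(sim_unknown)}")
            for k in ("effect_channels", "channel_ids", "condition_names"):
                if k in d["sim"]:
                    d["sim"][k] = tuple(d["sim"][k])
            d["sim"] = SimConfig(**d["sim"])
        if "stats" in d:
            d["stats"] = StatsParams(**d["stats"])
        if "band" in d:
            d["band"] = tuple(d["band"])
        return cls(**d)

    def content_hash(self) -> str:
        """Hash of the scientific configuration (paths and logging excluded)."""
        d = yaml.safe_load(self.to_yaml())
        d.pop("out_dir", None)
        d.pop("log_level", None)
        return hashlib.sha256(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:16]


def summarize_effect(cluster: Cluster, per_subject_diffs: np.ndarray) -> dict:
    """Subject-level summary of an effect over a cluster's members.

    ``per_subject_diffs`` has shape (n_subjects, n_channels, n_bins) holding
    each subject's condition-difference map.  Each subject's value is the
    mean over the cluster's (channel, bin) members; the block reports the
    signed mean, the mean of absolute values, and the positive/negative
    counts.
    """
    if not cluster.members:
        raise ValueError("summarize_effect: empty cluster")
    ch_idx, bin_idx = np.asarray(cluster.members).T
    vals = per_subject_diffs[:, ch_idx, bin_idx].mean(axis=1)
    return dict(
        per_subject=vals.tolist(),
        mean_signed=float(vals.mean()),
        mean_abs=float(np.abs(vals).mean()),
        n_positive=int((vals > 0).sum()),
        n_negative=int((vals < 0).sum()),
    )


def if_contrast_cohort(sim: SimConfig, n_subjects: int, seed: int,
                       params: StatsParams, band: BandSpec | None = None,
                       correct_only: bool = True):
    """Simulate a cohort and run only the instantaneous-frequency contrast.

    Convenience composition of the pipeline's simulate → IF → group-cluster
    stages (no spectra, bursts or decoding), for calibration studies and
    recovery checks.  Returns ``(result, effect, cohort)`` where ``result``
    is the :class:`~oscishift.stats.ClusterResult` of the condition contrast,
    ``effect`` the subject-level summary over the most prominent cluster
    (whole-window fallback when no cluster forms), and ``cohort`` the
    simulated subjects.
    """
    band = band if band is not None else BandSpec(13.0, 35.0)
    cohort = simulate_cohort(sim, n_subjects, seed=seed)
    graph = default_neighbor_graph(sim.channel_ids)
    summaries = []
    for rec in cohort:
        ifs = instantaneous_frequency(rec["decision"], band)
        summaries.append(subject_condition_if(ifs, correct_only=correct_only))
    valid = np.all([s["valid_mask"] for s in summaries], axis=0)
    cols = np.flatnonzero(valid.all(axis=0))
    time_axis = cohort[0]["decision"].time[cols]
    condA = np.stack([s["mean_if"][0][:, cols] for s in summaries])
    condB = np.stack([s["mean_if"][1][:, cols] for s in summaries])
    result = cluster_permutation_test(condB, condA, graph=graph, params=params,
                                      channel_ids=graph.channel_ids,
                                      bins=time_axis, bin_unit="s")
    diffs = condB - condA
    if result.clusters:
        effect = summarize_effect(result.clusters[0], diffs)
    else:
        whole = Cluster(
            members=[(c, b) for c in range(diffs.shape[1]) for b in range(diffs.shape[2])],
            mass=0.0, sign=0)
        effect = summarize_effect(whole, diffs)
        effect["fallback_whole_window"] = True
    return result, effect, cohort


def _spawn_seeds(master: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in np.random.SeedSequence(master).spawn(n)]


def _cluster_payload(result, channel_ids, bins) -> dict:
    clusters = []
    for c in result.clusters:
        b0, b1 = c.bin_range
        clusters.append(
            dict(
                p=float(c.p),
                mass=float(c.mass),
                sign=int(c.sign),
                n_members=len(c.members),
                channels=sorted({channel_ids[i] for i in c.channel_indices}),
                bin_lo=float(bins[b0]),
                bin_hi=float(bins[b1]),
                members=[[int(ci), int(bi)] for ci, bi in c.members],
            )
        )
    return dict(
        clusters=clusters,
        n_permutations=int(result.n_permutations),
        exact=bool(result.exact),
        threshold_t=float(result.threshold_t),
        n_significant=len(result.significant()),
    )


def run_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline and return the report dict.

    Writes under ``config.out_dir``: ``report.json``, ``report.txt``,
    ``tables/*.tsv``, ``intermediates/*.h5``, ``run.log``.
    """
    out = Path(config.out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    (out / "intermediates").mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level)
    if not any(isinstance(h, logging.StreamHandler) and h.stream is sys.stderr
               for h in log.handlers):
        log.addHandler(logging.StreamHandler(sys.stderr))

    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> dict:
    band = config.band_spec
    seeds = _spawn_seeds(config.seed, 4)
    sim_seed, stats_seed, decode_seed = seeds[0], seeds[1], seeds[2]

    # --- stage: simulate -------------------------------------------------
    try:
        log.info("stage=simulate seed=%d n_subjects=%d", sim_seed, config.n_subjects)
        cohort = simulate_cohort(config.sim, config.n_subjects, seed=sim_seed)
        graph = default_neighbor_graph(config.sim.channel_ids)
        write_neighbor_graph(graph, out / "intermediates" / "neighbors.json")
        for rec in cohort:
            sid = rec["subject_id"]
            write_epochs(rec["decision"], out / "intermediates" / f"{sid}_decision.h5")
            write_epochs(rec["baseline"], out / "intermediates" / f"{sid}_baseline.h5")
            (out / "intermediates" / f"{sid}_events.tsv").write_text(rec["events"].to_tsv())
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate", None, e) from e

    # --- stage: instantaneous frequency ---------------------------------
    if_subject = []
    for rec in cohort:
        sid = rec["subject_id"]
        try:
            log.info("stage=ifreq subject=%s", sid)
            ifs_dec = instantaneous_frequency(rec["decision"], band)
            ifs_base = instantaneous_frequency(rec["baseline"], band)
            summ = subject_condition_if(ifs_dec, correct_only=config.correct_only)
            base_all = np.ma.masked_array(ifs_base.ifreq, mask=~ifs_base.valid_mask)
            dec_all = np.ma.masked_array(ifs_dec.ifreq, mask=~ifs_dec.valid_mask)
            if_subject.append(
                dict(
                    subject_id=sid,
                    summary=summ,
                    decision_series=ifs_dec,
                    baseline_mean=np.ma.filled(base_all.mean(axis=(0, 2)), np.nan),
                    decision_mean=np.ma.filled(dec_all.mean(axis=(0, 2)), np.nan),
                )
            )
        except Exception as e:  # noqa: BLE001
            raise PipelineError("ifreq", sid, e) from e

    # --- stage: group IF contrast ----------------------------------------
    try:
        log.info("stage=if_contrast")
        valid = np.all([s["summary"]["valid_mask"] for s in if_subject], axis=0)
        cols = np.flatnonzero(valid.all(axis=0))
        time_axis = cohort[0]["decision"].time[cols]
        condA = np.stack([s["summary"]["mean_if"][0][:, cols] for s in if_subject])
        condB = np.stack([s["summary"]["mean_if"][1][:, cols] for s in if_subject])
        params = dataclasses.replace(config.stats, seed=stats_seed)
        if_res = cluster_permutation_test(
            condB, condA, graph=graph, params=params,
            channel_ids=graph.channel_ids, bins=time_axis, bin_unit="s",
        )
        diffs = condB - condA
        if if_res.clusters:
            effect = summarize_effect(if_res.clusters[0], diffs)
        else:
            # fallback: whole-window, all-channel average difference
            whole = Cluster(
                members=[(c, b) for c in range(diffs.shape[1]) for b in range(diffs.shape[2])],
                mass=0.0, sign=0,
            )
            effect = summarize_effect(whole, diffs)
            effect["fallback_whole_window"] = True
        # baseline-vs-decision window-mean IF, per channel
        base_mean = np.stack([s["baseline_mean"] for s in if_subject])[:, :, None]
        dec_mean = np.stack([s["decision_mean"] for s in if_subject])[:, :, None]
        base_res = cluster_permutation_test(
            dec_mean, base_mean, graph=graph, params=params,
            channel_ids=graph.channel_ids, bins=np.zeros(1), bin_unit="s",
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("if_contrast", None, e) from e

    # --- stage: spectra ---------------------------------------------------
    try:
        log.info("stage=spectra")
        mt_dec, mt_base, ir_frac, ir_osc = [], [], [], []
        pad_to = max(4.0, config.sim.window_len, config.sim.baseline_len)
        for rec in cohort:
            mt_dec.append(multitaper_psd(rec["decision"], pad_to=pad_to).average_trials())
            mt_base.append(multitaper_psd(rec["baseline"], pad_to=pad_to).average_trials())
            fr, os_ = irasa_decompose(rec["decision"], fband=band)
            ir_frac.append(fr.average_trials())
            ir_osc.append(os_.average_trials())
        params = dataclasses.replace(config.stats, seed=stats_seed)
        power_res = power_contrast(mt_dec, mt_base, graph=graph, params=params)
        irasa_res = power_contrast(ir_osc, ir_frac, graph=graph, params=params)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("spectra", None, e) from e

    # --- stage: bursts ----------------------------------------------------
    try:
        log.info("stage=bursts")
        burst_channel = config.burst_channel or config.sim.effect_channels[0]
        summaries = []
        for rec in cohort:
            tfr = morlet_tfr(rec["decision"])
            events = detect_spectral_events(tfr, band=band,
                                            fom_threshold=config.burst_fom_threshold)
            summaries.append(
                summarize_bursts(events, rec["decision"].trial_condition,
                                 window_len=config.sim.window_len,
                                 subject_id=rec["subject_id"], channel=burst_channel)
            )
        burst_res = burst_contrasts(summaries)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("bursts", None, e) from e

    # --- stage: decoding --------------------------------------------------
    try:
        log.info("stage=decode")
        dec_results = []
        dseeds = _spawn_seeds(decode_seed, len(cohort))
        for i, (rec, s) in enumerate(zip(cohort, if_subject)):
            ifs = s["decision_series"]
            sel = rec["decision"].trial_correct if config.correct_only else slice(None)
            feats = ifs.ifreq[sel][:, :, cols[:: config.decode_decimate]]
            labels = rec["decision"].trial_condition[sel]
            dec_results.append(
                time_resolved_decode(
                    feats, labels, times=time_axis[:: config.decode_decimate],
                    n_folds=config.decode_folds, n_repeats=config.decode_repeats,
                    seed=dseeds[i], subject_id=rec["subject_id"],
                )
            )
        params = dataclasses.replace(config.stats, seed=stats_seed, tail="pos")
        group_auc, auc_res = decode_cohort(dec_results, params=params)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("decode", None, e) from e

    # --- report -----------------------------------------------------------
    report = dict(
        provenance=dict(
            package_version=__version__,
            numpy_version=np.__version__,
            scipy_version=scipy.__version__,
            config_hash=config.content_hash(),
            seed=int(config.seed),
            n_subjects=int(config.n_subjects),
        ),
        if_contrast=dict(
            **_cluster_payload(if_res, graph.channel_ids, time_axis),
            effect=effect,
        ),
        if_baseline_contrast=_cluster_payload(base_res, graph.channel_ids, np.zeros(1)),
        power_contrast=_cluster_payload(power_res, graph.channel_ids, mt_dec[0].freqs),
        irasa_contrast=_cluster_payload(irasa_res, graph.channel_ids, ir_osc[0].freqs),
        bursts=dict(
            channel=burst_channel,
            rate_vs_zero=burst_res["rate_vs_zero"],
            freq_contrast=burst_res["freq_contrast"],
            n_excluded=burst_res["n_excluded"],
        ),
        decoding=dict(
            mean_auc=[float(v) for v in group_auc],
            times=[float(t) for t in time_axis[:: config.decode_decimate]],
            peak_auc=float(np.max(group_auc)),
            cluster=_cluster_payload(auc_res, ["auc"], time_axis[:: config.decode_decimate]),
        ),
    )
    _write_report(report, config, out, cohort, if_subject, summaries, dec_results)
    return report


def _write_report(report, config, out: Path, cohort, if_subject, summaries, dec_results):
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    (out / "config.yaml").write_text(config.to_yaml())

    lines = [f"oscishift {__version__} analysis report",
             f"config {report['provenance']['config_hash']} seed {config.seed} "
             f"n_subjects {config.n_subjects}", ""]
    eff = report["if_contrast"]["effect"]
    ifc = report["if_contrast"]
    lines.append("Instantaneous-frequency contrast (condition B - A):")
    if ifc["clusters"]:
        c = ifc["clusters"][0]
        lines.append(
            f"  most prominent cluster: p = {c['p']:.4g}, channels {c['channels']}, "
            f"{c['bin_lo']:.3f}-{c['bin_hi']:.3f} s, mass {c['mass']:.2f}"
        )
    else:
        lines.append("  no suprathreshold clusters")
    lines.append(
        f"  in-cluster shift: mean {eff['mean_signed']:+.3f} Hz, "
        f"|mean| {eff['mean_abs']:.3f} Hz, {eff['n_positive']} positive / "
        f"{eff['n_negative']} negative subjects"
    )
    lines.append("")
    lines.append(f"Power decision-vs-baseline: "
                 f"{report['power_contrast']['n_significant']} significant cluster(s)")
    lines.append(f"IRASA oscillatory-vs-fractal: "
                 f"{report['irasa_contrast']['n_significant']} significant cluster(s)")
    b = report["bursts"]
    lines.append("")
    lines.append(f"Bursts ({b['channel']}):")
    for cond, r in b["rate_vs_zero"].items():
        lines.append(
            f"  rate[{cond}] = {r['mean']:.2f}/window (SD {r['sd']:.2f}), "
            f"t[{r['df']}] = {r['t']:.1f}, p = {r['p']:.3g}"
        )
    if b["freq_contrast"]:
        fc = b["freq_contrast"]
        lines.append(
            f"  peak-frequency diff {fc['mean_diff']:+.3f} Hz "
            f"(|mean| {fc['mean_abs_diff']:.3f}), t[{fc['df']}] = {fc['t']:.2f}, "
            f"p = {fc['p']:.3g}, {fc['n_positive']}+/{fc['n_negative']}-"
        )
    d = report["decoding"]
    lines.append("")
    lines.append(
        f"Decoding: peak AUC {d['peak_auc']:.3f}, "
        f"{d['cluster']['n_significant']} significant cluster(s) vs 0.5"
    )
    (out / "report.txt").write_text("\n".join(lines) + "\n")

    # tables
    rows = ["subject_id\tsign_diff_hz\tabs_diff_hz"]
    for sid, v in zip([s["subject_id"] for s in if_subject],
                      report["if_contrast"]["effect"]["per_subject"]):
        rows.append(f"{sid}\t{v:+.6f}\t{abs(v):.6f}")
    (out / "tables" / "if_subject_diffs.tsv").write_text("\n".join(rows) + "\n")

    rows = ["subject_id\tcondition\tn_trials\tn_events\trate_per_window\trate_per_s\tmean_peak_freq_hz"]
    for pair in summaries:
        for s in pair:
            rows.append(
                f"{s.subject_id}\t{s.condition}\t{s.n_trials}\t{s.n_events}"
                f"\t{s.mean_rate:.4f}\t{s.rate_per_s:.4f}\t{s.mean_peak_freq:.4f}"
            )
    (out / "tables" / "burst_summaries.tsv").write_text("\n".join(rows) + "\n")

    rows = ["time_s\tmean_auc"]
    for t, a in zip(report["decoding"]["times"], report["decoding"]["mean_auc"]):
        rows.append(f"{t:.4f}\t{a:.6f}")
    (out / "tables" / "decoding_auc.tsv").write_text("\n".join(rows) + "\n")
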