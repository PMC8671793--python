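"""End-to-end study runner: synthesis -> preprocessing -> time-frequency ERD
-> ERP scoring -> statistics, as one reproducible, config-driven run.

A run is a pure function of its :class:`RunConfig` (including the seed): the
same config reproduces byte-identical tables and the same manifest hashes.
Derived per-subject results are cached on disk keyed by a hash of the config
and the subject/block ids, so partial reruns after a config change only
recompute what changed.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import erp, stats, synth, tfr
from . import preprocessing as pp

logger = logging.getLogger("affective_erd")

#: qualitative contrast pattern the default generator injects, as
#: (component, conditions A, conditions B, expected sign of mean(A) - mean(B)).
#: Signed amplitudes: a negative sign means the A deflection is the more
#: negative one (larger magnitude for negative-going components).
EXPECTED_DIRECTIONS: tuple = (
    ("N1", ("Sad", "Dis"), ("SadNeu", "DisNeu"), -1),
    ("N1", ("SadPos", "DisPos"), ("SadNeu", "DisNeu"), -1),
    ("EPN", ("Sad", "Dis"), ("SadNeu", "DisNeu"), -1),
    ("EPN", ("SadPos", "DisPos"), ("SadNeu", "DisNeu"), -1),
    ("P2", ("Dis",), ("Sad",), +1),
    ("P2", ("Dis",), ("DisNeu",), +1),
    ("N2", ("Dis",), ("DisNeu",), -1),
    ("P3", ("Dis",), ("Sad",), +1),
    ("P3", ("Dis",), ("DisPos",), +1),
    ("P3", ("Dis",), ("DisNeu",), +1),
    ("LPP", ("Dis",), ("Sad",), +1),
    ("LPP", ("Dis",), ("DisPos",), +1),
    ("LPP", ("Dis",), ("DisNeu",), +1),
)

#: a-priori pairwise comparisons (sadness vs disgust, each emotional
#: condition vs its block's neutral)
PLANNED_PAIRS: tuple = (
    ("Sad", "Dis"), ("Sad", "SadNeu"), ("SadPos", "SadNeu"),
    ("Dis", "DisNeu"), ("DisPos", "DisNeu"),
)


@dataclass(frozen=True)
class RunConfig:
    """Everything a study run depends on; fully YAML-serializable."""

    design: synth.StudyDesign = field(default_factory=synth.StudyDesign)
    effects: synth.EffectSpec = field(default_factory=synth.EffectSpec)
    preproc: pp.PreprocConfig = field(default_factory=pp.PreprocConfig)
    preproc_stages: tuple[str, ...] = pp.PIPELINE_ORDER
    wavelet: tfr.WaveletConfig = field(default_factory=tfr.alpha_wavelet_config)
    band_hz: tuple[float, float] = tfr.ALPHA_BAND
    test_s: tuple[float, float] = tfr.DEFAULT_TEST_S
    ref_s: tuple[float, float] = tfr.DEFAULT_REF_S
    erd_span_s: tuple[float, float] = (-2.0, 4.0)
    erp_span_s: tuple[float, float] = (-0.2, 4.0)
    #: channels entering the wavelet stage: "all" or an ROI name
    erd_channels: str = "all"
    #: ROI whose mean Di feeds the ERD ANOVA
    erd_roi: str = "parieto_occipital"
    run_tfr: bool = True
    #: ERP averaging restricted to behaviorally correct trials; ERD uses all
    erp_correct_only: bool = True
    erd_correct_only: bool = False
    make_plots: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "design": self.design.to_dict(),
            "effects": self.effects.to_dict(),
            "preproc": self.preproc.to_dict(),
            "preproc_stages": list(self.preproc_stages),
            "wavelet": self.wavelet.to_dict(),
            "band_hz": list(self.band_hz), "test_s": list(self.test_s),
            "ref_s": list(self.ref_s), "erd_span_s": list(self.erd_span_s),
            "erp_span_s": list(self.erp_span_s),
            "erd_channels": self.erd_channels, "erd_roi": self.erd_roi,
            "run_tfr": self.run_tfr,
            "erp_correct_only": self.erp_correct_only,
            "erd_correct_only": self.erd_correct_only,
            "make_plots": self.make_plots, "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            design=synth.StudyDesign.from_dict(d.get("design", {})),
            effects=synth.EffectSpec.from_dict(d.get("effects",
                                                     synth.EffectSpec().to_dict())),
            preproc=pp.PreprocConfig.from_dict(d.get("preproc", {})),
            preproc_stages=tuple(d.get("preproc_stages", pp.PIPELINE_ORDER)),
            wavelet=tfr.WaveletConfig.from_dict(
                d.get("wavelet", tfr.alpha_wavelet_config().to_dict())),
            band_hz=tuple(d.get("band_hz", tfr.ALPHA_BAND)),
            test_s=tuple(d.get("test_s", tfr.DEFAULT_TEST_S)),
            ref_s=tuple(d.get("ref_s", tfr.DEFAULT_REF_S)),
            erd_span_s=tuple(d.get("erd_span_s", (-2.0, 4.0))),
            erp_span_s=tuple(d.get("erp_span_s", (-0.2, 4.0))),
            erd_channels=d.get("erd_channels", "all"),
            erd_roi=d.get("erd_roi", "parieto_occipital"),
            run_tfr=d.get("run_tfr", True),
            erp_correct_only=d.get("erp_correct_only", True),
            erd_correct_only=d.get("erd_correct_only", False),
            make_plots=d.get("make_plots", False),
            seed=int(d.get("seed", 0)),
        )


def dump_config(cfg: RunConfig) -> str:
    return yaml.safe_dump(cfg.to_dict(), sort_keys=True,
                          default_flow_style=False)


def load_config(source) -> RunConfig:
    """Load a RunConfig from a YAML string or file path."""
    text = str(source)
    if "\n" not in text:
        try:
            if Path(text).exists():
                text = Path(text).read_text()
        except OSError:
            pass
    return RunConfig.from_dict(yaml.safe_load(text) or {})


@dataclass
class StudyReport:
    """All tables a run produces, plus the reproducibility manifest."""

    erd_table: pd.DataFrame
    scores: pd.DataFrame
    anova: dict
    contrasts: pd.DataFrame
    directions: pd.DataFrame
    manifest: dict
    alpha_course: pd.DataFrame | None = None


def _cache_key(cfg_yaml: str, subject: str, block: str) -> str:
    h = hashlib.sha256()
    h.update(cfg_yaml.encode())
    h.update(f"|{subject}|{block}".encode())
    return h.hexdigest()[:20]


def _sha(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def _subject_block_results(cfg: RunConfig, subject_idx: int, block: str,
                           montage: synth.Montage) -> dict:
    """Generate, clean, and analyze one subject x block recording."""
    rec = synth.generate_recording(cfg.design, cfg.effects, subject_idx,
                                   block, cfg.seed, montage=montage)
    if cfg.preproc_stages:
        rec, _ = pp.preprocess(rec, cfg.preproc, tuple(cfg.preproc_stages))

    out: dict = {"erd": [], "scores": [], "course": []}
    subject = rec.meta["subject"]

    if cfg.run_tfr:
        ep = erp.epoch(rec, cfg.erd_span_s, baseline_s=None)
        if cfg.erd_correct_only:
            ep = erp.EpochSet(ep.data[ep.correct], ep.times,
                              ep.labels[ep.correct], ep.correct[ep.correct],
                              ep.sfreq, ep.montage)
        channels = (montage.scalp_channels if cfg.erd_channels == "all"
                    else montage.roi_sets[cfg.erd_channels])
        for cond in synth.BLOCK_CONDITIONS[block]:
            sub = ep.select_conditions([cond])
            tfm = tfr.cwt_power(sub, cfg.wavelet, channels=channels,
                                condition=cond)
            erd_df = tfr.compute_erd(tfm, cfg.test_s, cfg.ref_s, cfg.band_hz,
                                     subject=subject, block=block)
            out["erd"].extend(erd_df.to_dict("records"))
            course = tfr.band_power_course(tfm, cfg.band_hz)
            roi = [c for c in montage.roi_sets[cfg.erd_roi] if c in tfm.channels]
            ridx = [list(tfm.channels).index(c) for c in roi]
            out["course"].append({
                "subject": subject, "block": block, "condition": cond,
                "times": tfm.times.tolist(),
                "power": course[ridx].mean(axis=0).tolist()})

    ep_erp = erp.epoch_and_baseline(rec, cfg.erp_span_s)
    scores = erp.score_epochset(ep_erp, correct_only=cfg.erp_correct_only,
                                subject=subject, block=block)
    out["scores"] = scores.to_dict("records")
    return out


def run_study(cfg: RunConfig, out_dir=None) -> StudyReport:
    """Run the full pipeline for every subject x block of the design.

    If ``out_dir`` is given, tidy CSV tables, the stats JSON, the config, a
    manifest with content hashes, and (optionally) figures are written there,
    and per-subject derived results are cached for cheap partial reruns.
    """
    t_start = time.time()
    montage = synth.default_montage()
    cfg_yaml = dump_config(cfg)
    out_dir = Path(out_dir) if out_dir is not None else None
    cache_dir = out_dir / "cache" if out_dir is not None else None
    if cache_dir is not None:
        cache_dir.mkdir(parents=True, exist_ok=True)

    erd_rows: list[dict] = []
    score_rows: list[dict] = []
    course_rows: list[dict] = []
    blocks = synth.BLOCKS[: cfg.design.n_blocks]
    for subject_idx in range(1, cfg.design.n_subjects + 1):
        for block in blocks:
            key = _cache_key(cfg_yaml, f"S{subject_idx:02d}", block)
            cache_file = cache_dir / f"{key}.json" if cache_dir else None
            if cache_file is not None and cache_file.exists():
                payload = json.loads(cache_file.read_text())
            else:
                t0 = time.time()
                try:
                    payload = _subject_block_results(cfg, subject_idx, block,
                                                     montage)
                except Exception as err:
                    raise RuntimeError(
                        f"stage failure for subject S{subject_idx:02d} "
                        f"block {block}: {err}") from err
                logger.info("subject S%02d %s analyzed in %.1f s",
                            subject_idx, block, time.time() - t0)
                if cache_file is not None:
                    cache_file.write_text(json.dumps(payload))
            erd_rows.extend(payload["erd"])
            score_rows.extend(payload["scores"])
            course_rows.extend(payload["course"])

    erd_table = pd.DataFrame(erd_rows)
    scores = pd.DataFrame(score_rows)
    anova, contrasts = _stats_battery(cfg, erd_table, scores, montage)
    directions = direction_table(scores)
    alpha_course = _grand_course(course_rows) if course_rows else None

    manifest = {
        "seed": cfg.seed,
        "config_sha256": _sha(cfg_yaml),
        "erd_sha256": _sha(erd_table.to_csv(index=False)),
        "scores_sha256": _sha(scores.to_csv(index=False)),
        "n_subjects": cfg.design.n_subjects,
        "blocks": list(blocks),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "wall_time_s": round(time.time() - t_start, 2),
    }
    report = StudyReport(erd_table=erd_table, scores=scores, anova=anova,
                         contrasts=contrasts, directions=directions,
                         manifest=manifest, alpha_course=alpha_course)
    if out_dir is not None:
        _write_report(report, cfg, cfg_yaml, out_dir, montage)
    return report


def _grand_course(course_rows: list[dict]) -> pd.DataFrame:
    frames = []
    for row in course_rows:
        frames.append(pd.DataFrame({"time_s": row["times"],
                                    "power": row["power"],
                                    "condition": row["condition"]}))
    df = pd.concat(frames, ignore_index=True)
    return (df.groupby(["condition", "time_s"], as_index=False)["power"]
            .mean())


def _stats_battery(cfg: RunConfig, erd_table: pd.DataFrame,
                   scores: pd.DataFrame, montage: synth.Montage
                   ) -> tuple[dict, pd.DataFrame]:
    anova: dict = {}
    contrast_results = []

    if len(erd_table):
        roi = montage.roi_sets[cfg.erd_roi]
        sub = erd_table[erd_table["channel"].isin(roi)]
        per = (sub.groupby(["subject", "block", "condition"], as_index=False)
               ["Di"].mean())
        per["valence"] = per["condition"].map(synth.VALENCE)
        table = per.rename(columns={"block": "group", "Di": "value"})
        anova["erd"] = {k: v.to_dict() for k, v in
                        stats.twoway_anova(table).items()}
        by_val = {v: g["value"].to_numpy()
                  for v, g in table.groupby("valence")}
        contrast_results += [
            dataclasses.replace(r, family="erd_posthoc_valence")
            for r in stats.posthoc_bonferroni(by_val)]
        by_cond = {c: g["value"].to_numpy()
                   for c, g in table.groupby("condition")}
        contrast_results += [
            dataclasses.replace(r, family="erd_planned")
            for r in stats.planned_contrasts(by_cond, PLANNED_PAIRS)]

    for comp, g in scores.groupby("component"):
        tbl = g.rename(columns={"block": "group",
                                "mean_amplitude_uv": "value"}).copy()
        tbl["valence"] = tbl["condition"].map(synth.VALENCE)
        anova[f"erp_{comp}"] = {k: v.to_dict() for k, v in
                                stats.twoway_anova(tbl).items()}
        by_cond = {c: gg["value"].to_numpy()
                   for c, gg in tbl.groupby("condition")}
        pairs = [p for p in PLANNED_PAIRS
                 if p[0] in by_cond and p[1] in by_cond]
        contrast_results += [
            dataclasses.replace(r, family=f"erp_{comp}_planned")
            for r in stats.planned_contrasts(by_cond, pairs)]
        by_val = {v: gg["value"].to_numpy()
                  for v, gg in tbl.groupby("valence")}
        contrast_results += [
            dataclasses.replace(r, family=f"erp_{comp}_posthoc_valence")
            for r in stats.posthoc_bonferroni(by_val)]

    return anova, stats.contrasts_frame(contrast_results)


def direction_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Observed sign of every expected qualitative contrast.

    Per-subject scores are averaged within each condition set (equal subject
    weighting), then the sets are compared; ``ok`` records whether the
    observed difference has the injected direction.
    """
    per = (scores.groupby(["component", "condition", "subject"], as_index=False)
           ["mean_amplitude_uv"].mean())
    rows = []
    for comp, conds_a, conds_b, sign in EXPECTED_DIRECTIONS:
        sub = per[per["component"] == comp]
        mean_a = sub[sub["condition"].isin(conds_a)]["mean_amplitude_uv"].mean()
        mean_b = sub[sub["condition"].isin(conds_b)]["mean_amplitude_uv"].mean()
        diff = float(mean_a - mean_b)
        rows.append({"component": comp,
                     "set_a": "+".join(conds_a), "set_b": "+".join(conds_b),
                     "expected_sign": sign, "mean_difference_uv": diff,
                     "ok": bool(np.sign(diff) == sign)})
    return pd.DataFrame(rows)


def _write_report(report: StudyReport, cfg: RunConfig, cfg_yaml: str,
                  out_dir: Path, montage: synth.Montage) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.erd_table.to_csv(out_dir / "erd.csv", index=False)
    report.scores.to_csv(out_dir / "scores.csv", index=False)
    report.contrasts.to_csv(out_dir / "contrasts.csv", index=False)
    report.directions.to_csv(out_dir / "directions.csv", index=False)
    (out_dir / "stats.json").write_text(json.dumps(report.anova, indent=1))
    (out_dir / "config.yaml").write_text(cfg_yaml)
    (out_dir / "manifest.json").write_text(json.dumps(report.manifest, indent=1))
    if report.alpha_course is not None:
        report.alpha_course.to_csv(out_dir / "alpha_course.csv", index=False)
    if cfg.make_plots:
        _write_plots(report, cfg, out_dir, montage)


def _write_plots(report: StudyReport, cfg: RunConfig, out_dir: Path,
                 montage: synth.Montage) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    maps_dir = out_dir / "maps"
    maps_dir.mkdir(exist_ok=True)
    if report.alpha_course is not None:
        fig, ax = plt.subplots(figsize=(6, 3.5))
        for cond, g in report.alpha_course.groupby("condition"):
            ax.plot(g["time_s"], g["power"], label=cond)
        ax.axvline(0.0, color="k", lw=0.5)
        ax.set_xlabel("time from picture onset (s)")
        ax.set_ylabel("alpha power (uV$^2$)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(maps_dir / "alpha_course.png", dpi=120)
        plt.close(fig)
    if len(report.erd_table) and cfg.erd_channels == "all":
        grand = (report.erd_table
                 .groupby(["condition", "channel"], as_index=False)["Di"].mean())
        grand["erd_strength"] = -grand["Di"]
        for cond, g in grand.groupby("condition"):
            topo = tfr.erd_topography(g, montage)
            fig, ax = plt.subplots(figsize=(4, 4))
            im = ax.pcolormesh(topo.grid_x, topo.grid_y, topo.values,
                               shading="auto")
            ax.add_patch(plt.Circle((0, 0), 1.0, fill=False, color="k"))
            ax.set_aspect("equal")
            ax.set_title(f"ERD strength: {cond}")
            fig.colorbar(im, ax=ax, shrink=0.8)
            fig.savefig(maps_dir / f"erd_topo_{cond}.png", dpi=120)
            plt.close(fig)
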