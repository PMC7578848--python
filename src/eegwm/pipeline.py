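"""End-to-end orchestration: simulate -> features -> decode -> report.

A single :class:`RunConfig` (YAML-loadable) carries every analysis
constant — band tables, 0.5-Hz high-pass, 200-ms edge trim, 80-10-10
splits, 200 repetitions — so deviations from the defaults are always
explicit in the run manifest.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bands import CFC_PAIRS, POWER_BANDS
from .cfc import CFCGrid, cfc_features
from .connectivity import connectivity_features
from .decoding import (
    FeatureMatrix,
    make_targets,
    permutation_chance,
    repeated_accuracy,
)
from .io import CHANNELS_64, build_adjacency, read_recording, write_recording
from .segmentation import highpass, segment_acquisition
from .spectral import assemble_power_tensor, realign_power_features
from .stats import one_way_anova, render_tables, two_way_anova
from .synthetic import CohortConfig, generate_cohort

log = logging.getLogger("eegwm")

FAMILIES = ("power", "connectivity", "cfc")


class PipelineError(Exception):
    pass


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    families: tuple[str, ...] = FAMILIES
    connectivity_bands: tuple[str, ...] = tuple(POWER_BANDS.names)
    cfc_pairs: tuple[str, ...] = tuple(CFC_PAIRS)
    schemes: tuple[str, ...] = ("four_class", "modality", "load")
    reps: int = 200
    seed: int = 0
    highpass_hz: float = 0.5
    trim_s: float = 0.2
    psd_window_s: float = 2.0
    cfc_grid: CFCGrid = field(default_factory=CFCGrid)
    out_dir: str = "eegwm_run"

    def validate(self) -> None:
        self.cohort.validate()
        for fam in self.families:
            if fam not in FAMILIES:
                raise PipelineError(f"unknown feature family {fam!r}")
        if self.reps < 1:
            raise PipelineError("reps must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in (raw.pop("cohort", {}) or {}).items()
        })
        grid_kw = raw.pop("cfc_grid", {}) or {}
        grid = CFCGrid(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in grid_kw.items()
        })
        kwargs = {
            k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
        }
        return cls(cohort=cohort, cfc_grid=grid, **kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _derived_seed(master: int, *parts: str) -> int:
    tags = [zlib.crc32(p.encode()) for p in parts]
    ss = np.random.SeedSequence([int(master), *tags])
    return int(ss.generate_state(1)[0] % 2**31)


def simulate_stage(cfg: RunConfig, out: Path) -> list[tuple[Path, Path]]:
    """Generate the cohort and persist it as EDF + sidecars."""
    data_dir = out / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    pairs, truth = generate_cohort(cfg.cohort)
    paths = []
    for rec_v, rec_av in pairs:
        for rec in (rec_v, rec_av):
            stem = f"{rec.participant_id}_{rec.modality_tag}"
            edf = data_dir / f"{stem}.edf"
            events = data_dir / f"{stem}_events.tsv"
            write_recording(rec, edf, events)
            paths.append((edf, events))
    truth.to_tsv(data_dir / "ground_truth.tsv")
    return paths


def _load_runs(cfg: RunConfig, paths: list[tuple[Path, Path]]):
    runs = {}
    for edf, events in paths:
        rec = highpass(read_recording(edf, events), cfg.highpass_hz)
        runs[(rec.participant_id, rec.modality_tag)] = segment_acquisition(rec)
    return runs


def features_stage(
    cfg: RunConfig, paths: list[tuple[Path, Path]], out: Path
) -> dict[tuple[str, str], FeatureMatrix]:
    """Compute the requested feature families and write one TSV per table."""
    feat_dir = out / "features"
    feat_dir.mkdir(parents=True, exist_ok=True)
    runs = _load_runs(cfg, paths)
    participants = sorted({pid for pid, _ in runs})
    ordered_runs = [
        runs[(pid, mod)] for pid in participants for mod in ("visual", "audiovisual")
    ]
    matrices: dict[tuple[str, str], FeatureMatrix] = {}
    if "power" in cfg.families:
        tensors = {
            pid: assemble_power_tensor(
                runs[(pid, "visual")], runs[(pid, "audiovisual")],
                window_s=cfg.psd_window_s,
            )
            for pid in participants
        }
        for band, fm in realign_power_features(tensors, CHANNELS_64).items():
            matrices[("power", band)] = fm
    if "connectivity" in cfg.families:
        adjacency = build_adjacency(CHANNELS_64)
        for band in cfg.connectivity_bands:
            matrices[("connectivity", band)] = connectivity_features(
                ordered_runs, band, adjacency, CHANNELS_64, trim_s=cfg.trim_s
            )
    if "cfc" in cfg.families:
        for pair in cfg.cfc_pairs:
            matrices[("cfc", pair)] = cfc_features(
                ordered_runs, pair, grid=cfg.cfc_grid,
                channel_names=CHANNELS_64, trim_s=cfg.trim_s,
            )
    for (family, band), fm in matrices.items():
        fm.to_tsv(feat_dir / f"{family}_{band}.tsv")
    return matrices


def decode_stage(
    cfg: RunConfig, matrices: dict[tuple[str, str], FeatureMatrix], out: Path
) -> pd.DataFrame:
    """Run the repeated-split SVM plus its permutation null for every
    feature table and target scheme; returns a long accuracy table."""
    dec_dir = out / "decoding"
    dec_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (family, band), fm in matrices.items():
        for scheme in cfg.schemes:
            y = make_targets(fm.meta, scheme)
            seed = _derived_seed(cfg.seed, family, band, scheme)
            for dist in (
                repeated_accuracy(fm, y, cfg.reps, seed, scheme),
                permutation_chance(fm, y, cfg.reps, seed, scheme),
            ):
                for rep, acc in enumerate(dist.accuracies):
                    rows.append(
                        {
                            "family": family,
                            "band": band,
                            "scheme": scheme,
                            "condition": dist.condition,
                            "rep": rep,
                            "accuracy": acc,
                        }
                    )
                conf = dist.confusions.sum(axis=0)
                pd.DataFrame(
                    conf, index=dist.labels, columns=dist.labels
                ).to_csv(
                    dec_dir / f"confusion_{family}_{band}_{scheme}_{dist.condition}.tsv",
                    sep="\t",
                )
    table = pd.DataFrame(rows)
    table.to_csv(dec_dir / "accuracies.tsv", sep="\t", index=False)
    return table


def report_stage(cfg: RunConfig, accuracies: pd.DataFrame, out: Path) -> list[Path]:
    rep_dir = out / "report"
    rep_dir.mkdir(parents=True, exist_ok=True)
    summaries, anovas = {}, {}
    for family, fam_df in accuracies.groupby("family"):
        per_scheme_summary, per_scheme_anova = {}, {}
        for scheme, s_df in fam_df.groupby("scheme"):
            actual = s_df[s_df["condition"] == "actual"]
            per_scheme_summary[scheme] = {
                band: (b_df["accuracy"].mean(), b_df["accuracy"].std(ddof=1))
                for band, b_df in actual.groupby("band")
            }
            groups = {
                band: b_df["accuracy"].to_numpy()
                for band, b_df in actual.groupby("band")
            }
            if len(groups) >= 2 and min(len(g) for g in groups.values()) >= 2:
                per_scheme_anova[scheme] = one_way_anova(groups)
                both = two_way_anova(
                    s_df["accuracy"].to_numpy(),
                    s_df["band"].to_numpy(),
                    s_df["condition"].to_numpy(),
                )
                per_scheme_anova[f"{scheme}_x_condition"] = both["condition"]
        summaries[family] = per_scheme_summary
        if per_scheme_anova:
            anovas[family] = per_scheme_anova
    return render_tables(summaries, anovas, rep_dir)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage; the manifest suffices to reproduce the run."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    cfg.to_yaml(out / "manifest.yaml")
    try:
        t0 = time.time()
        log.info("stage simulate: cohort of %d participants, seed %d",
                 cfg.cohort.n_participants, cfg.cohort.seed)
        paths = _run_stage("simulate", simulate_stage, cfg, out)
        log.info("stage simulate done in %.1f s", time.time() - t0)

        t0 = time.time()
        log.info("stage features: families %s", list(cfg.families))
        matrices = _run_stage("features", features_stage, cfg, paths, out)
        log.info("stage features done in %.1f s", time.time() - t0)

        t0 = time.time()
        log.info("stage decode: %d reps, seed %d", cfg.reps, cfg.seed)
        accuracies = _run_stage("decode", decode_stage, cfg, matrices, out)
        log.info("stage decode done in %.1f s", time.time() - t0)

        t0 = time.time()
        _run_stage("report", report_stage, cfg, accuracies, out)
        log.info("stage report done in %.1f s", time.time() - t0)
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


def _run_stage(name, fn, cfg, *args):
    try:
        return fn(cfg, *args)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc
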