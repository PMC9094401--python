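"""End-to-end orchestration: simulate/load -> transform -> decode -> evaluate.

A single :class:`RunConfig` drives the whole chain and every random choice
derives from one global seed by stable hashing of (seed, stage, voxel, band,
repetition), so adding a voxel or band never perturbs another's results.  A
run manifest (config echo, seeds, versions, failing stage if any) is always
written, even when a stage fails.

The CNN stage dominates run time; ``decoder="stub"`` replaces it with a
deterministic pseudo-scorer so the bookkeeping of a full 25-voxel x 32-band
design (800 method pairs, 825 models with the raw-series models) can be
exercised in seconds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alff import alff_table, paired_t, wavelet_alff, alff_decode_scores, DegenerateStatisticError
from .bold_io import (
    LabeledDataset,
    extract_voxel_series,
    load_peak_table,
    mni_to_index,
    read_series_table,
    read_volume_series,
    write_series_table,
)
from .decoder import CnnHyper, DecodingResult, TrainTestSplit, make_split, train_repeated
from .evaluation import (
    DEFAULT_AUC_THRESHOLD,
    auc,
    fit_calibration,
    rank_models,
    summarize_comparison,
)
from .synthetic import SimConfig, simulate_dataset
from .wavelet import Scalogram, build_band_grid, cwt_transform

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "derive_seed", "results_to_frame", "frame_to_results"]

ORIGINAL_LABEL = "original"


def derive_seed(global_seed: int, stage: str, *parts) -> np.random.SeedSequence:
    """Stable per-stage seed stream from hashed (seed, stage, part...) keys."""
    ints = [int(global_seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())]
    ints += [zlib.crc32(str(p).encode()) for p in parts]
    return np.random.SeedSequence(ints)


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run (exactly one input source)."""

    # input source: exactly one of the three
    sim: SimConfig | None = None
    series_table: str | None = None
    nifti_manifest: str | None = None  # TSV: path, subject_id, state_label
    peak_table: str | None = None  # required with nifti_manifest

    # band grid
    f_start_hz: float = 0.003
    f_step_hz: float = 0.01
    n_bands: int = 32

    # decoding
    hyper: CnnHyper = field(default_factory=CnnHyper)
    test_fraction: float = 0.25
    split_mode: str = "sample"
    decoder: str = "cnn"  # "cnn" or "stub"
    include_original: bool = True
    bands: tuple[int, ...] | None = None  # subset of band indices; None = all

    # evaluation
    auc_threshold: float = DEFAULT_AUC_THRESHOLD
    ttest_scope: str = "full"  # "full" sample or "test" split only

    out_dir: str = "voxeldecode_run"
    seed: int = 0

    def __post_init__(self) -> None:
        sources = [self.sim is not None, self.series_table is not None,
                   self.nifti_manifest is not None]
        if sum(sources) != 1:
            raise ValueError("exactly one input source (sim | series_table | nifti_manifest)")
        if self.nifti_manifest is not None and self.peak_table is None:
            raise ValueError("nifti_manifest requires a peak_table")
        if self.decoder not in ("cnn", "stub"):
            raise ValueError("decoder must be 'cnn' or 'stub'")
        if self.ttest_scope not in ("full", "test"):
            raise ValueError("ttest_scope must be 'full' or 'test'")


def _load_datasets(config: RunConfig) -> dict[str, LabeledDataset]:
    """Resolve the input source into one labeled dataset per voxel."""
    if config.sim is not None:
        sim = replace(config.sim, seed=_seed_int(derive_seed(config.seed, "simulate")))
        return {"sim": simulate_dataset(sim)}
    if config.series_table is not None:
        ds = read_series_table(config.series_table)
        by_voxel: dict[str, LabeledDataset] = {}
        for s in ds.series:
            by_voxel.setdefault(s.voxel_id, LabeledDataset()).series.append(s)
        return by_voxel
    manifest = pd.read_csv(config.nifti_manifest, sep="\t")
    peaks = load_peak_table(config.peak_table)
    by_voxel = {f"peak{p.id:02d}_{p.region_name}": LabeledDataset() for p in peaks}
    for row in manifest.itertuples(index=False):
        volume = read_volume_series(row.path)
        for p in peaks:
            idx = mni_to_index(volume.affine, p.mni_xyz, shape=volume.shape)
            key = f"peak{p.id:02d}_{p.region_name}"
            by_voxel[key].series.append(
                extract_voxel_series(volume, idx, subject_id=str(row.subject_id),
                                     state_label=str(row.state_label), voxel_id=key)
            )
    return by_voxel


def _stub_result(config: RunConfig, voxel: str, band_label: str, method: str,
                 split_seed: int) -> DecodingResult:
    """Deterministic pseudo decoding result for dry-run bookkeeping."""
    rng = np.random.default_rng(derive_seed(config.seed, "stub", voxel, band_label, method))
    reps = config.hyper.n_repetitions if method == "cnn" else 1
    aucs = rng.uniform(0.35, 0.95, size=reps)
    return DecodingResult(
        voxel_id=voxel, band_label=band_label, method=method,
        auc_mean=float(aucs.mean()), auc_per_repetition=aucs,
        split_seed=split_seed, n_repetitions=reps,
    )


def _alff_result(band_values: np.ndarray, labels: np.ndarray, split: TrainTestSplit,
                 voxel: str, band_label: str) -> DecodingResult:
    scores = alff_decode_scores(
        band_values[split.train_indices], labels[split.train_indices],
        band_values[split.test_indices],
    )
    a = auc(scores, labels[split.test_indices])
    return DecodingResult(
        voxel_id=voxel, band_label=band_label, method="alff",
        auc_mean=a, auc_per_repetition=np.array([a]),
        split_seed=split.split_seed, n_repetitions=1,
    )


def results_to_frame(results: list[DecodingResult]) -> pd.DataFrame:
    rows = [
        {
            "voxel_id": r.voxel_id, "band_label": r.band_label, "method": r.method,
            "auc_mean": r.auc_mean, "n_repetitions": r.n_repetitions,
            "split_seed": r.split_seed, "monitor": r.monitor,
            "auc_reps": ",".join(f"{a:.6g}" for a in r.auc_per_repetition),
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def frame_to_results(df: pd.DataFrame) -> list[DecodingResult]:
    out = []
    for row in df.itertuples(index=False):
        reps = np.array([float(v) for v in str(row.auc_reps).split(",")])
        out.append(
            DecodingResult(
                voxel_id=str(row.voxel_id), band_label=str(row.band_label),
                method=str(row.method), auc_mean=float(reps.mean()),
                auc_per_repetition=reps, split_seed=int(row.split_seed),
                n_repetitions=int(row.n_repetitions), monitor=str(row.monitor),
            )
        )
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run the full chain and write all outputs under ``config.out_dir``.

    Returns a summary dict (also serialized as JSON).  Any stage failure is
    re-raised after the manifest records the failing stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _config_dict(config),
        "versions": {"voxeldecode": __version__, "numpy": np.__version__},
        "started_unix": time.time(),
        "status": "running",
        "stage": None,
    }

    def _write_manifest() -> None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    try:
        manifest["stage"] = "load"
        _write_manifest()
        datasets = _load_datasets(config)
        logger.info("loaded %d voxel dataset(s)", len(datasets))
        if config.sim is not None:
            write_series_table(datasets["sim"], out / "series.tsv")

        manifest["stage"] = "transform"
        first = next(iter(datasets.values()))
        grid = build_band_grid(config.f_start_hz, config.f_step_hz, config.n_bands,
                               first.tr_seconds)
        band_indices = list(config.bands) if config.bands is not None else list(range(grid.n_bands))
        scalograms: dict[str, list[Scalogram]] = {}
        for voxel, ds in datasets.items():
            ds.validate_rectangular()
            scalograms[voxel] = [cwt_transform(s, grid) for s in ds.series]

        manifest["stage"] = "alff"
        alff_frames = []
        for voxel, sgs in scalograms.items():
            df = alff_table(sgs)
            df.insert(0, "voxel", voxel)
            alff_frames.append(df)
        alff_df = pd.concat(alff_frames, ignore_index=True)
        alff_df.to_csv(out / "alff.tsv", sep="\t", index=False)

        manifest["stage"] = "split"
        splits = {
            voxel: make_split(
                ds, test_fraction=config.test_fraction, mode=config.split_mode,
                seed=_seed_int(derive_seed(config.seed, "split", voxel)),
            )
            for voxel, ds in datasets.items()
        }

        manifest["stage"] = "decode"
        cnn_results: list[DecodingResult] = []
        alff_results: list[DecodingResult] = []
        for voxel, ds in datasets.items():
            labels = np.asarray(ds.labels)
            split = splits[voxel]
            coef = np.stack([sg.coefficients for sg in scalograms[voxel]])  # (N, bands, T)
            for b in band_indices:
                label = grid.band_labels()[b]
                band_vals = np.array([wavelet_alff(sg, b) for sg in scalograms[voxel]])
                alff_results.append(_alff_result(band_vals, labels, split, voxel, label))
                if config.decoder == "stub":
                    cnn_results.append(_stub_result(config, voxel, label, "cnn",
                                                    split.split_seed))
                else:
                    hyper = replace(config.hyper,
                                    seed=_seed_int(derive_seed(config.seed, "cnn", voxel, label)))
                    cnn_results.append(
                        train_repeated(split, coef[:, b, :], labels, hyper,
                                       voxel_id=voxel, band_label=label)
                    )
                logger.info("decoded %s band %s", voxel, label)
            if config.include_original:
                if config.decoder == "stub":
                    cnn_results.append(_stub_result(config, voxel, ORIGINAL_LABEL, "cnn",
                                                    split.split_seed))
                else:
                    hyper = replace(config.hyper,
                                    seed=_seed_int(derive_seed(config.seed, "cnn", voxel,
                                                               ORIGINAL_LABEL)))
                    cnn_results.append(
                        train_repeated(split, ds.values_matrix(), labels, hyper,
                                       voxel_id=voxel, band_label=ORIGINAL_LABEL)
                    )
        results_to_frame(cnn_results + alff_results).to_csv(
            out / "decoding_results.tsv", sep="\t", index=False)

        manifest["stage"] = "ttests"
        ttest_rows = []
        for voxel, ds in datasets.items():
            labels = np.asarray(ds.labels)
            subjects = np.asarray(ds.subjects)
            scope = (np.arange(labels.size) if config.ttest_scope == "full"
                     else splits[voxel].test_indices)
            for b in band_indices:
                vals = np.array([wavelet_alff(sg, b) for sg in scalograms[voxel]])
                pairs_a, pairs_b = _pair_by_subject(vals[scope], labels[scope], subjects[scope])
                try:
                    stat = paired_t(pairs_a, pairs_b)
                    ttest_rows.append({"voxel": voxel, "band_label": grid.band_labels()[b],
                                       "t_value": stat.t_value, "df": stat.df,
                                       "p_value": stat.p_value})
                except (DegenerateStatisticError, ValueError) as exc:
                    logger.warning("t-test skipped for %s band %d: %s", voxel, b, exc)
        ttest_df = pd.DataFrame(ttest_rows)
        ttest_df.to_csv(out / "ttests.tsv", sep="\t", index=False)

        manifest["stage"] = "evaluate"
        band_cnn = [r for r in cnn_results if r.band_label != ORIGINAL_LABEL]
        summary_obj = summarize_comparison(band_cnn, alff_results, config.auc_threshold)
        summary = summary_obj.to_dict()
        summary["n_models_total"] = len(cnn_results) + len(alff_results)
        summary["n_cnn_models"] = len(cnn_results)
        if config.include_original:
            _, mean_rank = rank_models(cnn_results, n_expected=len(band_indices) + 1)
            summary["mean_rank_original"] = mean_rank
        calibration = None
        alff_by_key = {(r.voxel_id, r.band_label): r.auc_mean for r in alff_results}
        t_by_key = {(row["voxel"], row["band_label"]): abs(row["t_value"])
                    for row in ttest_rows}
        common = sorted(set(alff_by_key) & set(t_by_key))
        if len(common) >= 2:
            aucs = np.array([alff_by_key[k] for k in common])
            ts = np.array([t_by_key[k] for k in common])
            if np.ptp(aucs) > 1e-12:
                model = fit_calibration(aucs, ts)
                calibration = dataclasses.asdict(model)
                (out / "calibration.json").write_text(json.dumps(calibration, indent=2))
        summary["calibration"] = calibration
        (out / "summary.json").write_text(json.dumps(summary, indent=2))

        manifest["stage"] = "done"
        manifest["status"] = "ok"
        manifest["finished_unix"] = time.time()
        _write_manifest()
        return summary
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"stage {manifest['stage']}: {exc}"
        _write_manifest()
        raise


def _pair_by_subject(values: np.ndarray, labels: np.ndarray, subjects: np.ndarray):
    """Align SI and VG values of the same subject; drops incomplete subjects."""
    si = {s: v for s, v, l in zip(subjects, values, labels) if l == "SI"}
    vg = {s: v for s, v, l in zip(subjects, values, labels) if l == "VG"}
    common = sorted(set(si) & set(vg))
    return (np.array([si[s] for s in common]), np.array([vg[s] for s in common]))


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d
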