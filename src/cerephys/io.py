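"""File formats, configuration, and the end-to-end pipeline driver.

Interchange formats are deliberately boring: UTF-8 comma-separated CSV with
a header row for spike times and metadata, HDF5 for voltage traces, JSON
for statistical reports and the run manifest, YAML for configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import group_stats, spike_metrics, synthdata
from .types import CohortTable, InvalidSpecification, SpikeTrain, VoltageTrace

__all__ = [
    "write_spike_csv",
    "read_spike_csv",
    "write_metadata_csv",
    "read_metadata_csv",
    "write_trace_h5",
    "read_trace_h5",
    "load_config",
    "cohort_spec_from_config",
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
]

log = logging.getLogger("cerephys")

SPIKE_COLUMNS = ["cell_id", "unit_type", "time_s"]


def write_spike_csv(cohort: CohortTable, path: str | Path) -> Path:
    """Spike-time table: cell_id, unit_type {ss,cs,cn}, time_s (6 decimals)."""
    path = Path(path)
    df = cohort.spikes_frame()
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_spike_csv(path: str | Path) -> tuple[dict[str, dict[str, np.ndarray]], list[str]]:
    """Read a spike-time CSV into {cell_id: {unit_type: sorted times}}.

    Returns (trains, warnings).  Unsorted times are sorted with a warning,
    duplicated events de-duplicated with a warning; malformed rows are
    rejected with their line numbers; negative times are a parse error.
    """
    path = Path(path)
    notes: list[str] = []
    try:
        df = pd.read_csv(path, dtype={"cell_id": str, "unit_type": str})
    except pd.errors.EmptyDataError:
        notes.append("empty spike file")
        warnings.warn(notes[-1])
        return {}, notes
    if df.empty:
        notes.append("empty spike file")
        return {}, notes
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidSpecification(f"spike CSV missing columns: {missing}")
    times = pd.to_numeric(df["time_s"], errors="coerce")
    bad = times.isna() | ~df["unit_type"].isin(["ss", "cs", "cn"])
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        notes.append(f"rejected {int(bad.sum())} malformed rows at lines {lines}")
        df = df[~bad]
        times = times[~bad]
    if (times < 0).any():
        raise InvalidSpecification("negative spike times in input")
    df = df.assign(time_s=times)
    out: dict[str, dict[str, np.ndarray]] = {}
    for (cid, unit), sub in df.groupby(["cell_id", "unit_type"]):
        t = sub["time_s"].to_numpy()
        if np.any(np.diff(t) < 0):
            notes.append(f"unsorted times for {cid}/{unit}; sorted")
            t = np.sort(t)
        tu = np.unique(t)
        if tu.size < t.size:
            notes.append(f"de-duplicated {t.size - tu.size} events for {cid}/{unit}")
        out.setdefault(cid, {})[unit] = tu
    for msg in notes:
        warnings.warn(msg)
    return out, notes


def write_metadata_csv(cohort: CohortTable, path: str | Path) -> Path:
    path = Path(path)
    cohort.metadata_frame().to_csv(path, index=False)
    return path


def read_metadata_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"cell_id": str})


def trains_from_tables(spikes: dict[str, dict[str, np.ndarray]],
                       meta: pd.DataFrame) -> CohortTable:
    """Rebuild a cohort from spike + metadata tables (metrics not yet set)."""
    from .types import CellRecord

    cells = []
    for _, row in meta.iterrows():
        cid = row["cell_id"]
        trains = {
            unit: SpikeTrain(t, float(row["duration_s"]))
            for unit, t in spikes.get(cid, {}).items()
        }
        cells.append(CellRecord(
            cell_id=cid, genotype=row["genotype"], state=row["state"],
            cell_type=row["cell_type"], depth_mm=float(row["depth_mm"]),
            days_post_surgery=float(row["days_post_surgery"]),
            duration_s=float(row["duration_s"]), seed=int(row["seed"]),
            trains=trains,
        ))
    return CohortTable(cells)


def write_trace_h5(trace: VoltageTrace, path: str | Path) -> Path:
    """HDF5 container: /trace (float32 μV) with fs_hz / filter_band_hz
    attributes and /ground_truth/<unit> spike-time datasets."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        d = f.create_dataset("trace", data=trace.samples.astype(np.float32))
        d.attrs["fs_hz"] = trace.fs_hz
        if trace.filter_band_hz is not None:
            d.attrs["filter_band_hz"] = list(trace.filter_band_hz)
        g = f.create_group("ground_truth")
        for unit, t in trace.ground_truth.items():
            g.create_dataset(unit, data=np.asarray(t, dtype=float))
    return path


def read_trace_h5(path: str | Path) -> VoltageTrace:
    with h5py.File(path, "r") as f:
        d = f["trace"]
        band = d.attrs.get("filter_band_hz")
        gt = {k: f["ground_truth"][k][()] for k in f.get("ground_truth", {})}
        return VoltageTrace(
            samples=d[()], fs_hz=float(d.attrs["fs_hz"]),
            filter_band_hz=None if band is None else (float(band[0]), float(band[1])),
            ground_truth=gt,
        )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


_COHORT_FACTORIES = {
    "awake_purkinje": synthdata.awake_purkinje_cohort,
    "anesthetized_purkinje": synthdata.anesthetized_purkinje_cohort,
    "awake_nuclear": synthdata.awake_nuclear_cohort,
}


def cohort_spec_from_config(cfg: dict, master_seed: int) -> synthdata.CohortSpec:
    """Build a CohortSpec from a config mapping.

    Either ``preset`` names one of the built-in study conditions
    (awake_purkinje, anesthetized_purkinje, awake_nuclear), optionally with
    ``n_cells_per_group`` / ``duration_s`` overrides, or an explicit
    ``base``/``effects`` section spells the processes out.
    """
    cohort = cfg.get("cohort", {})
    preset = cohort.get("preset", "awake_purkinje")
    if preset not in _COHORT_FACTORIES:
        raise InvalidSpecification(f"unknown cohort preset {preset!r}")
    kwargs = {k: cohort[k] for k in ("n_cells_per_group", "duration_s")
              if k in cohort}
    spec = _COHORT_FACTORIES[preset](master_seed, **kwargs)
    return spec


@dataclass
class PipelineConfig:
    """Stage toggles and options for a full run."""

    out_dir: Path
    master_seed: int
    cohort: synthdata.CohortSpec
    simulate: bool = True
    metrics: bool = True
    stats: bool = True
    unit_types: tuple[str, ...] = ("ss", "cs")
    fdr: float = 0.2
    alpha: float = 0.05
    exclude_cs_spanning: bool = False

    @classmethod
    def from_file(cls, path: str | Path, out_dir: str | Path,
                  master_seed: int | None = None) -> "PipelineConfig":
        cfg = load_config(path) or {}
        seed = int(cfg.get("master_seed", 0) if master_seed is None else master_seed)
        spec = cohort_spec_from_config(cfg, seed)
        stats_cfg = cfg.get("stats", {})
        units = tuple(stats_cfg.get(
            "unit_types", ("cn",) if spec.cell_type == "nuclear" else ("ss", "cs")))
        stages = cfg.get("stages", {})
        return cls(
            out_dir=Path(out_dir), master_seed=seed, cohort=spec,
            simulate=bool(stages.get("simulate", True)),
            metrics=bool(stages.get("metrics", True)),
            stats=bool(stages.get("stats", True)),
            unit_types=units,
            fdr=float(stats_cfg.get("fdr", 0.2)),
            alpha=float(stats_cfg.get("alpha", 0.05)),
        )


@dataclass
class RunManifest:
    """Reproducibility record: config digest and per-output checksums."""

    master_seed: int
    config_hash: str
    outputs: dict[str, str] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(
            {"master_seed": self.master_seed, "config_hash": self.config_hash,
             "outputs": self.outputs, "skipped": self.skipped}, indent=2))
        return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """simulate -> metrics -> stats, writing every stage product to out_dir.

    Any stage failure propagates after earlier outputs are on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_repr = repr((config.master_seed, config.cohort, config.unit_types,
                     config.fdr, config.alpha))
    manifest = RunManifest(
        master_seed=config.master_seed,
        config_hash=hashlib.sha256(cfg_repr.encode()).hexdigest(),
    )

    cohort = None
    if config.simulate:
        log.info("simulating cohort (%d cells/group)", config.cohort.n_cells_per_group)
        cohort = synthdata.gen_cohort(config.cohort)
        for name, writer in (("spikes.csv", write_spike_csv),
                             ("metadata.csv", write_metadata_csv)):
            p = writer(cohort, out / name)
            manifest.outputs[name] = _sha256(p)
    else:
        manifest.skipped.append("simulate")
        spikes, _ = read_spike_csv(out / "spikes.csv")
        cohort = trains_from_tables(spikes, read_metadata_csv(out / "metadata.csv"))

    metrics = None
    if config.metrics:
        metrics = spike_metrics.metrics_frame(cohort, config.exclude_cs_spanning)
        p = out / "metrics.csv"
        metrics.to_csv(p, index=False, float_format="%.6f")
        manifest.outputs["metrics.csv"] = _sha256(p)
        summary = spike_metrics.cohort_summary(metrics)
        p = out / "group_summary.csv"
        summary.to_csv(p, index=False, float_format="%.6f")
        manifest.outputs["group_summary.csv"] = _sha256(p)
    else:
        manifest.skipped.append("metrics")

    if config.stats:
        if metrics is None:
            raise InvalidSpecification("stats stage requires the metrics stage")
        present = set(metrics["unit_type"])
        for unit in config.unit_types:
            if unit not in present:
                manifest.skipped.append(f"stats:{unit}")
                continue
            report = group_stats.analysis_workflow(
                metrics, unit, alpha=config.alpha, fdr=config.fdr)
            p = out / f"stats_{unit}.json"
            p.write_text(report.to_json())
            manifest.outputs[p.name] = _sha256(p)
    else:
        manifest.skipped.append("stats")

    manifest.write(out / "manifest.json")
    return manifest


def render_report(stats_json: str | Path) -> str:
    """Human-readable summary of a stats JSON report."""
    data = json.loads(Path(stats_json).read_text())
    lines = [f"Unit type: {data['unit_type']}   "
             f"(alpha={data['alpha']}, BH FDR={data['fdr']}, "
             f"{data['n_dropped']} cells dropped)"]
    for pred, entry in data["predictors"].items():
        if "skipped" in entry:
            lines.append(f"  {pred}: skipped ({entry['skipped']})")
            continue
        m = entry["manova"]
        g1, g2 = m["df_groups"]
        lines.append(
            f"  {pred}: Wilk's lambda({g1},{g2})={m['wilks_lambda']:.4f}, "
            f"P={m['p']:.4g} -> "
            + ("pairwise tests" if entry["gate_passed"] else "no pairwise tests")
        )
        for pw in entry.get("pairwise", []):
            verdict = "rejected" if pw["rejected"] else "not rejected"
            lines.append(
                f"      {pw['response']}: |z|={abs(pw['z']):.2f} "
                f"({pw['direction']}), P={pw['p']:.4g}, "
                f"BH critical={pw['bh_critical']:.4g} -> {verdict}"
            )
    for w in data.get("warnings", []):
        lines.append(f"  note: {w}")
    return "\n".join(lines)
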