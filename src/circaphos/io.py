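"""Table and FASTA readers/writers plus the end-to-end pipeline driver.

Traces travel as long-format CSV (one row per time point), phospho tables
as wide CSV (one row per peptide occurrence, one column per sample),
labels as two-column CSV, proteins as FASTA, and run manifests as JSON.
The pipeline configuration is a strict YAML mapping: unknown keys are
rejected so typos fail loudly, and every random stage takes an explicit
seed recorded in the manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import motif, pharm, phospho, rhythm, synthdata
from .errors import ConfigError, SchemaError

__all__ = [
    "TRACE_COLUMNS",
    "read_traces",
    "write_traces",
    "read_phospho_table",
    "read_fasta",
    "read_labels",
    "fits_to_frame",
    "PipelineConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

TRACE_COLUMNS = [
    "time_h",
    "lum",
    "well",
    "plate",
    "line",
    "treatment",
    "dose_uM",
    "pulse_start_zt",
    "replicate",
]

_META_COLUMNS = TRACE_COLUMNS[2:]


def write_traces(traces, path) -> None:
    """Write traces to long-format CSV (columns: TRACE_COLUMNS)."""
    frames = []
    for tr in traces:
        md = tr.metadata
        frames.append(
            pd.DataFrame(
                {
                    "time_h": tr.times,
                    "lum": tr.values,
                    "well": md.get("well", ""),
                    "plate": md.get("plate", ""),
                    "line": md.get("line", ""),
                    "treatment": md.get("treatment", ""),
                    "dose_uM": md.get("dose_uM", 0.0),
                    "pulse_start_zt": md.get("pulse_start_zt", ""),
                    "replicate": md.get("replicate", ""),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces(path) -> list:
    """Read long-format trace CSV into LuminescenceTrace objects.

    Traces are keyed by (plate, well); rows with non-finite luminescence
    are dropped with a logged count.  Missing required columns raise
    :class:`SchemaError` naming the column.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trace table missing column(s): {missing}")
    bad = ~np.isfinite(df["lum"].to_numpy(dtype=float))
    if bad.any():
        logger.warning("dropping %d rows with non-finite luminescence", bad.sum())
        df = df[~bad]
    traces = []
    for (plate, well), grp in df.groupby(["plate", "well"], sort=True):
        grp = grp.sort_values("time_h")
        md = {c: grp.iloc[0][c] for c in _META_COLUMNS}
        traces.append(
            rhythm.LuminescenceTrace(
                grp["time_h"].to_numpy(dtype=float),
                grp["lum"].to_numpy(dtype=float),
                md,
            )
        )
    return traces


def read_phospho_table(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read an occurrence-level phospho CSV.

    ``column_map`` renames foreign column layouts (e.g. supplementary
    spreadsheets exported to CSV) onto the native schema: a mapping of
    source name -> native name for the identification columns; columns not
    named in the map and not identification columns are taken as sample
    abundances.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in phospho.ID_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"phospho table missing column(s): {missing}")
    return df


def read_fasta(path) -> dict:
    """protein_id -> sequence from a FASTA file."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_labels(path) -> pd.DataFrame:
    """Imported target labels: CSV with columns site_key, is_target."""
    df = pd.read_csv(path)
    for col in ("site_key", "is_target"):
        if col not in df.columns:
            raise SchemaError(f"labels table missing column {col!r}")
    df["is_target"] = df["is_target"].astype(bool)
    return df


def fits_to_frame(fits) -> pd.DataFrame:
    """Rhythm fits as a flat table (one row per well)."""
    rows = []
    for f in fits:
        md = f.metadata
        rows.append(
            {
                "well": md.get("well", ""),
                "plate": md.get("plate", ""),
                "line": md.get("line", ""),
                "treatment": md.get("treatment", ""),
                "dose_uM": md.get("dose_uM", 0.0),
                "pulse_start_zt": md.get("pulse_start_zt", ""),
                "period_h": f.period,
                "phase_h": f.phase,
                "amplitude": f.amplitude,
                "rss": f.rss,
                "rhythmic": f.rhythmic_flag,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pipeline configuration and driver


@dataclass
class PipelineConfig:
    """End-to-end run configuration; round-trips through YAML.

    Unknown keys in the YAML are rejected.  All seeds are explicit so a
    manifest fully reproduces a run.
    """

    out_dir: str = "circaphos_out"
    seed: int = 0
    # rhythm stage
    window: tuple = (16.0, 40.0)
    grid_step: float = 0.05
    n_harmonics: int = 3
    burn_in: float = 0.0
    # synthetic trace stage
    n_replicates: int = 8
    trace_noise_sd: float = 60.0
    doses_uM: tuple = (0.0, 0.5, 1.0, 2.0, 4.0)
    max_period_effect_h: float = 7.7
    prc_pulse_starts: tuple = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0)
    prc_max_delay_min: float = -150.0
    # phospho stage
    n_proteins: int = 200
    spike_fraction: float = 0.1
    n_phospho_replicates: int = 5
    p_threshold: float = 0.05
    fc_threshold: float = 1.5
    # enrichment stage
    n_permutations: int = 100_000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("window", "doses_uM", "prc_pulse_starts"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for key in ("window", "doses_uM", "prc_pulse_starts"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _hill_effect(dose: float, max_effect: float, ec50: float = 1.0, h: float = 2.0):
    if dose <= 0:
        return 0.0
    return max_effect / (1.0 + (ec50 / dose) ** h)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the synthetic end-to-end analysis and write all outputs.

    Stages: simulate dose plates -> fit rhythms -> dose-response; simulate
    pulse experiments -> PRC; simulate phospho table -> collate ->
    differential -> motif enrichment.  A JSON manifest (parameters, seeds,
    row counts, timings) is written alongside the stage outputs.  Stage
    failures propagate with the stage named; outputs of completed stages
    remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    fit_kw = dict(
        window=tuple(config.window),
        grid_step=config.grid_step,
        n_harmonics=config.n_harmonics,
        burn_in=config.burn_in,
    )
    stage = "simulate-traces"
    try:
        t0 = time.time()
        base = synthdata.TraceParams(noise_sd=config.trace_noise_sd)
        design = synthdata.PlateDesign(
            n_replicates=config.n_replicates,
            conditions=tuple(
                ("CCA1-LUC", "PF-670462" if d > 0 else "vehicle", d, "", "")
                for d in config.doses_uM
            ),
        )
        traces = synthdata.simulate_plate(
            base,
            design,
            seed=config.seed,
            period_effect=lambda c: _hill_effect(c[2], config.max_period_effect_h),
        )
        write_traces(traces, out / "traces.csv")
        manifest["stages"][stage] = {
            "n_traces": len(traces),
            "seconds": round(time.time() - t0, 3),
        }

        stage = "fit-rhythm"
        t0 = time.time()
        fits = [rhythm.estimate_period(tr, **fit_kw) for tr in traces]
        fits_to_frame(fits).to_csv(out / "fits.csv", index=False)
        manifest["stages"][stage] = {
            "n_fits": len(fits),
            "seconds": round(time.time() - t0, 3),
        }

        stage = "dose-response"
        t0 = time.time()
        treated = [f for f in fits if f.metadata.get("dose_uM", 0.0) > 0]
        controls = [f for f in fits if f.metadata.get("dose_uM", 0.0) == 0]
        dr = pharm.dose_response(treated, controls)
        pd.DataFrame([p.__dict__ for p in dr]).to_csv(out / "dose_response.csv",
                                                      index=False)
        manifest["stages"][stage] = {
            "n_doses": len(dr),
            "seconds": round(time.time() - t0, 3),
        }

        stage = "prc"
        t0 = time.time()
        def shift_fn(zt):
            # delay-only curve peaking at ZT12
            return config.prc_max_delay_min * max(
                0.0, np.cos(np.pi * (zt - 12.0) / 12.0)
            )

        experiments = []
        for i, zt in enumerate(config.prc_pulse_starts):
            tr_t, tr_v = synthdata.simulate_prc_experiment(
                base, zt, shift_fn, seed=config.seed + 1000 + i,
                n_replicates=config.n_replicates,
            )
            fits_t = [rhythm.estimate_period(t, **fit_kw) for t in tr_t]
            fits_v = [rhythm.estimate_period(t, **fit_kw) for t in tr_v]
            experiments.append((zt, fits_t, fits_v))
        prc = pharm.build_prc(experiments, period_ref=base.period)
        pd.DataFrame([p.__dict__ for p in prc]).to_csv(out / "prc.csv", index=False)
        manifest["stages"][stage] = {
            "n_points": len(prc),
            "seconds": round(time.time() - t0, 3),
        }

        stage = "phospho"
        t0 = time.time()
        pparams = synthdata.PhosphoSimParams(
            n_proteins=config.n_proteins,
            spike_fraction=config.spike_fraction,
            n_replicates_per_group=config.n_phospho_replicates,
        )
        table, truth = synthdata.simulate_phospho_table(pparams, seed=config.seed + 2)
        table.to_csv(out / "phospho_occurrences.csv", index=False)
        truth.to_csv(out / "phospho_truth.csv", index=False)
        sites = phospho.collate_sites(table)
        g_a, g_b = pparams.group_names
        n = pparams.n_replicates_per_group
        group_a = [f"{g_a}_{r}" for r in range(1, n + 1)]
        group_b = [f"{g_b}_{r}" for r in range(1, n + 1)]
        diff = phospho.differential_sites(
            sites, group_a, group_b,
            p_threshold=config.p_threshold, fc_threshold=config.fc_threshold,
        )
        diff_df = phospho.results_frame(diff)
        diff_df.to_csv(out / "differential.csv")
        manifest["stages"][stage] = {
            "n_sites": len(diff),
            "n_significant": int(diff_df["significant"].sum()),
            "seconds": round(time.time() - t0, 3),
        }

        stage = "motif-enrich"
        t0 = time.time()
        truth_idx = truth.set_index("site_key")
        tested = diff_df[diff_df["testable"]]
        fc = tested["fold_change"].to_numpy()
        labels = truth_idx.loc[tested.index, "is_motif_target"].to_numpy()
        enr = motif.permutation_enrichment(
            fc, labels, n_permutations=config.n_permutations,
            seed=config.seed + 3,
        )
        (out / "enrichment.json").write_text(json.dumps(enr.__dict__, indent=2))
        manifest["stages"][stage] = {
            "p_two_tailed": enr.p_two_tailed,
            "observed_statistic": enr.observed_statistic,
            "seconds": round(time.time() - t0, 3),
        }
    except Exception:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        logger.error("pipeline failed at stage %s", stage)
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
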