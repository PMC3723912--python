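"""Synthetic luminescence plates and phospho-peptide tables with ground truth.

The trace generator emulates damped, drifting circadian bioluminescence
reporters observed under constant light:

    x(t) = baseline + drift*t
           + amplitude * exp(-damping_rate * t) * cos(2*pi*(t - phase)/period)
           + N(0, noise_sd^2)

The phospho generator emulates label-free phospho-peptide quantification
tables: site-level raw abundances are log-normal, a spiked fraction of
sites carries a true fold change in the comparison group, each site is
emitted as one or more peptide occurrence rows (charge states, missed
cleavages) whose per-replicate abundances sum exactly to the site value,
and a motif label is assigned at a higher rate among up-spiked sites.

Every generator is a pure function of (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .errors import ParameterError
from .rhythm import LuminescenceTrace

__all__ = [
    "TraceParams",
    "PlateDesign",
    "PhosphoSimParams",
    "simulate_trace",
    "simulate_plate",
    "simulate_prc_experiment",
    "simulate_phospho_table",
]


@dataclass(frozen=True)
class TraceParams:
    """Generative parameters of one bioluminescence trace.

    ``phase`` is the time (hours) of the first peak of the rhythmic
    component.  Defaults: hourly sampling for 120 h (>= 4 cycles), a 24 h
    period and mild damping, matching typical reporter-imaging cadence.
    """

    baseline: float = 1000.0
    drift: float = 0.0  # counts/hour
    amplitude: float = 300.0
    damping_rate: float = 0.005  # 1/hour, >= 0
    period: float = 24.0
    phase: float = 6.0
    noise_sd: float = 0.0
    sampling_interval: float = 1.0
    duration: float = 120.0

    def validate(self) -> None:
        if self.period <= 0:
            raise ParameterError("period must be > 0")
        if self.damping_rate < 0:
            raise ParameterError("damping_rate must be >= 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.duration < 2 * self.period:
            raise ParameterError(
                "duration must cover at least two cycles (duration >= 2*period)"
            )
        if self.sampling_interval > self.period / 8:
            raise ParameterError(
                "sampling_interval must be <= period/8 for harmonic fitting"
            )


@dataclass(frozen=True)
class PlateDesign:
    """Replicated condition layout with treated/control pairing.

    ``conditions`` are (line, treatment, dose_uM, pulse_start, pulse_duration)
    tuples.  Pairing follows the bench convention of comparing each treated
    well against the identical well position on a control plate, with 8
    replicates by default.
    """

    n_replicates: int = 8
    conditions: tuple = ()
    pairing: str = "same_well_other_plate"

    def validate(self) -> None:
        if self.n_replicates < 2:
            raise ParameterError("n_replicates must be >= 2")


@dataclass(frozen=True)
class PhosphoSimParams:
    """Generative parameters of a phospho-peptide quantification table.

    ``abundance_log_sd`` is the replicate-level noise on the natural-log
    scale; ``site_log_sd`` spreads the per-site base abundances.  Group
    size defaults to 5 replicates per group, the design used for
    label-free phospho-proteomic comparisons here.
    """

    n_proteins: int = 200
    sites_per_protein: tuple = ("poisson1", 1.0)  # 1 + Poisson(lam)
    n_replicates_per_group: int = 5
    abundance_log_mean: float = 9.0
    abundance_log_sd: float = 0.25
    site_log_sd: float = 1.0
    spike_fraction: float = 0.1
    spike_fc_distribution: tuple = ("lognormal", 1.0, 0.3)  # exp(N(mu, sd)), or ("fixed", fc)
    spike_up_fraction: float = 0.85
    motif_label_rate_spiked_up: float = 0.5
    motif_label_rate_background: float = 0.1
    peptide_multiplicity: tuple = ("poisson1", 0.7)  # occurrences per site
    missing_rate: float = 0.0
    group_names: tuple = ("control", "case")

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ParameterError("n_proteins must be >= 1")
        if self.n_replicates_per_group < 2:
            raise ParameterError("need >= 2 replicates per group")
        if not 0 <= self.spike_fraction <= 1:
            raise ParameterError("spike_fraction must be in [0, 1]")
        for name, rate in (
            ("motif_label_rate_spiked_up", self.motif_label_rate_spiked_up),
            ("motif_label_rate_background", self.motif_label_rate_background),
            ("missing_rate", self.missing_rate),
            ("spike_up_fraction", self.spike_up_fraction),
        ):
            if not 0 <= rate <= 1:
                raise ParameterError(f"{name} must be in [0, 1]")


def _rhythmic_component(params: TraceParams, t: np.ndarray) -> np.ndarray:
    envelope = params.amplitude * np.exp(-params.damping_rate * t)
    return envelope * np.cos(2.0 * np.pi * (t - params.phase) / params.period)


def simulate_trace(
    params: TraceParams, seed: int, metadata: dict | None = None, t_start: float = 0.0
) -> LuminescenceTrace:
    """Generate one damped-cosine trace with Gaussian noise.

    ``t_start`` offsets the first sample (e.g. to begin recording after an
    inhibitor washout); the phase remains referenced to t = 0.
    Identical (params, seed) give bitwise-identical traces.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    t = t_start + np.arange(0.0, params.duration + 0.5 * params.sampling_interval,
                            params.sampling_interval)
    x = params.baseline + params.drift * t + _rhythmic_component(params, t)
    if params.noise_sd > 0:
        x = x + rng.normal(0.0, params.noise_sd, size=t.size)
    md = dict(metadata or {})
    md.setdefault("true_period", params.period)
    md.setdefault("true_phase", params.phase % params.period)
    md.setdefault("true_amplitude", params.amplitude)
    return LuminescenceTrace(t, x, md)


def simulate_plate(
    base: TraceParams,
    design: PlateDesign,
    seed: int,
    period_effect: Callable[[tuple], float] | None = None,
) -> list[LuminescenceTrace]:
    """Generate a plate of replicate wells for each condition.

    ``period_effect(condition)`` returns the period lengthening (hours)
    applied to that condition's wells; None means no effect.  Wells are
    named A1, A2, ... within each condition's plate so treated/control
    pairing by well position is well defined.
    """
    design.validate()
    traces = []
    ss = np.random.SeedSequence(seed)
    for ci, cond in enumerate(design.conditions):
        line, treatment, dose, pulse_start, pulse_duration = cond
        dT = period_effect(cond) if period_effect else 0.0
        p = TraceParams(
            baseline=base.baseline,
            drift=base.drift,
            amplitude=base.amplitude,
            damping_rate=base.damping_rate,
            period=base.period + dT,
            phase=base.phase,
            noise_sd=base.noise_sd,
            sampling_interval=base.sampling_interval,
            duration=base.duration,
        )
        child = ss.spawn(1)[0]
        for rep, s in enumerate(child.generate_state(design.n_replicates), start=1):
            md = {
                "line": line,
                "treatment": treatment,
                "dose_uM": dose,
                "pulse_start_zt": pulse_start,
                "plate": f"P{ci + 1}",
                "well": f"A{rep}",
                "replicate": rep,
            }
            traces.append(simulate_trace(p, int(s % (2**31)), metadata=md))
    return traces


def simulate_prc_experiment(
    base: TraceParams,
    pulse_start: float,
    true_shift_function: Callable[[float], float],
    seed: int,
    n_replicates: int = 8,
    pulse_duration: float = 4.0,
    compound: str = "PF-670462",
) -> tuple[list[LuminescenceTrace], list[LuminescenceTrace]]:
    """Generate paired treated/vehicle plates for one pulse start time.

    ``true_shift_function(pulse_start)`` returns the phase change in
    minutes, delays negative: a shift of -150 min makes the treated peak
    2.5 h later than the vehicle peak.  Both plates resume recording after
    washout (pulse_start + pulse_duration); truth is recorded in each
    trace's metadata.
    """
    if not 0 <= pulse_start <= base.period:
        raise ParameterError("pulse_start must lie within one circadian cycle")
    shift_min = float(true_shift_function(pulse_start))
    washout = pulse_start + pulse_duration
    treated_phase = base.phase - shift_min / 60.0  # delay (<0 min) -> later peak

    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 * n_replicates)
    out = {}
    for label, phase, offset in (
        ("vehicle", base.phase, 0),
        ("treated", treated_phase, n_replicates),
    ):
        p = TraceParams(
            baseline=base.baseline,
            drift=base.drift,
            amplitude=base.amplitude,
            damping_rate=base.damping_rate,
            period=base.period,
            phase=phase,
            noise_sd=base.noise_sd,
            sampling_interval=base.sampling_interval,
            duration=base.duration,
        )
        plate = []
        for rep in range(1, n_replicates + 1):
            md = {
                "line": "CCA1-LUC",
                "treatment": compound if label == "treated" else "vehicle",
                "dose_uM": 4.0 if label == "treated" else 0.0,
                "pulse_start_zt": pulse_start,
                "pulse_duration_h": pulse_duration,
                "plate": "T1" if label == "treated" else "V1",
                "well": f"A{rep}",
                "replicate": rep,
                "true_shift_min": shift_min if label == "treated" else 0.0,
            }
            plate.append(
                simulate_trace(
                    p,
                    int(seeds[offset + rep - 1] % (2**31)),
                    metadata=md,
                    t_start=washout,
                )
            )
        out[label] = plate
    return out["treated"], out["vehicle"]


def _draw_counts(spec: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = spec[0]
    if kind == "fixed":
        return np.full(n, int(spec[1]))
    if kind == "poisson1":
        return 1 + rng.poisson(float(spec[1]), size=n)
    raise ParameterError(f"unknown count distribution {spec!r}")


def _draw_fc(spec: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = spec[0]
    if kind == "fixed":
        return np.full(n, float(spec[1]))
    if kind == "lognormal":
        return np.exp(rng.normal(float(spec[1]), float(spec[2]), size=n))
    raise ParameterError(f"unknown fold-change distribution {spec!r}")


_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def simulate_phospho_table(
    params: PhosphoSimParams, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a phospho-peptide occurrence table plus its ground truth.

    Returns ``(table, truth)``.  ``table`` has one row per quantified
    peptide occurrence with identification columns and one abundance column
    per sample (``<group>_<rep>``).  ``truth`` has one row per site:
    ``site_key, protein_id, position, is_spiked, true_fc, is_motif_target``
    and the true site-level abundance of each sample.

    Occurrence abundances of a site split its replicate value by fixed
    Dirichlet weights, so per-sample sums over occurrences reproduce the
    site-level truth exactly (conservation).
    """
    params.validate()
    rng = np.random.default_rng(seed)
    g_a, g_b = params.group_names
    n_rep = params.n_replicates_per_group
    samples = [f"{g_a}_{r}" for r in range(1, n_rep + 1)] + [
        f"{g_b}_{r}" for r in range(1, n_rep + 1)
    ]

    n_sites_per_prot = _draw_counts(params.sites_per_protein, params.n_proteins, rng)
    prot_ids = [f"OT{p + 1:05d}" for p in range(params.n_proteins)]
    site_prot = np.repeat(np.arange(params.n_proteins), n_sites_per_prot)
    n_sites = site_prot.size

    # Distinct positions within each protein so site keys are unique.
    positions = np.concatenate(
        [8 + rng.choice(400, size=k, replace=False) for k in n_sites_per_prot]
    )
    residues = rng.choice(["S", "T", "Y"], size=n_sites, p=[0.7, 0.25, 0.05])

    is_spiked = rng.random(n_sites) < params.spike_fraction
    fc = np.ones(n_sites)
    n_spiked = int(is_spiked.sum())
    if n_spiked:
        mag = _draw_fc(params.spike_fc_distribution, n_spiked, rng)
        mag = np.maximum(mag, 1.0 + 1e-9)
        up = rng.random(n_spiked) < params.spike_up_fraction
        fc[is_spiked] = np.where(up, mag, 1.0 / mag)

    is_up = is_spiked & (fc > 1.0)
    label_rate = np.where(
        is_up, params.motif_label_rate_spiked_up, params.motif_label_rate_background
    )
    is_target = rng.random(n_sites) < label_rate

    base_log = rng.normal(params.abundance_log_mean, params.site_log_sd, size=n_sites)
    noise = rng.normal(0.0, params.abundance_log_sd, size=(n_sites, 2 * n_rep))
    site_ab = np.exp(base_log[:, None] + noise)
    site_ab[:, n_rep:] *= fc[:, None]  # group B carries the true effect

    if params.missing_rate > 0:
        site_ab[rng.random(site_ab.shape) < params.missing_rate] = np.nan

    site_keys = [
        f"{prot_ids[p]}_{pos}" for p, pos in zip(site_prot, positions)
    ]
    truth = pd.DataFrame(
        {
            "site_key": site_keys,
            "protein_id": [prot_ids[p] for p in site_prot],
            "position": positions,
            "residue": residues,
            "is_spiked": is_spiked,
            "true_fc": fc,
            "is_motif_target": is_target,
        }
    )
    truth[samples] = site_ab

    mult = _draw_counts(params.peptide_multiplicity, n_sites, rng)
    rows = []
    for i in range(n_sites):
        m = int(mult[i])
        w = rng.dirichlet(np.ones(m)) if m > 1 else np.ones(1)
        seq_len = 9 + int(rng.integers(0, 8))
        pep = "".join(rng.choice(_AA, size=seq_len))
        for j in range(m):
            rows.append(
                {
                    "protein_id": prot_ids[site_prot[i]],
                    "peptide_seq": pep,
                    "site_positions": str(int(positions[i])),
                    "residue": residues[i],
                    "charge": int(2 + (j % 3)),
                    "missed_cuts": int(j % 2),
                    "other_mods": "",
                    **{s: site_ab[i, k] * w[j] for k, s in enumerate(samples)},
                }
            )
    table = pd.DataFrame(rows)
    return table, truth
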