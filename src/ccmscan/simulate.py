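"""Synthetic LC-MS run generator with known ground truth.

Emulates what the acquisition delivers to the processing pipeline:
Gaussian chromatographic peaks at the panel retention times, centroid
m/z jittered by a few ppm around the theoretical values, half-normal
baseline noise, a nine-level 1:2 calibration ladder, per-sample
preparation scale factors (removable by internal-standard ratioing),
pooled QC injections every six samples, and group-wise fold changes
mimicking five metabolic-inhibitor scenarios.  Everything is driven by
one integer seed; identical specs give byte-identical output.

It does not emulate peak tailing, ion suppression or isotopologue fine
structure — see the methods note for what that implies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ms_io import FeatureTable
from .panel import Panel, PanelEntry
from .quantify import CalibrationLadder, make_ladder

__all__ = [
    "RunSpec",
    "ScenarioSpec",
    "DEFAULT_SCENARIOS",
    "default_scenarios",
    "simulate_ladder",
    "simulate_study",
]

_SQRT2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class RunSpec:
    """Instrument/run-level simulation parameters.

    rt_step: chromatographic sampling interval, min (peak region).
    peak_sigma_min: Gaussian peak SD, min.
    mz_jitter_ppm: SD of per-centroid mass error, ppm.
    noise_sd: baseline noise SD, counts.
    response_factor_mean / _log_sd: lognormal per-compound response
        factors, counts*min per uM.
    prep_log_sd: SD of log per-sample preparation scale factor (0.2
        corresponds to ~20% sample-to-sample variation).
    drift_pct_per_injection: multiplicative sensitivity drift.
    is_nominal_uM: constant spiked level of every internal standard.
    window_min: half-width of the emitted RT window per compound, min.
    """

    seed: int = 0
    rt_step: float = 0.01
    peak_sigma_min: float = 0.05
    mz_jitter_ppm: float = 1.0
    noise_sd: float = 30.0
    response_factor_mean: float = 3000.0
    response_factor_log_sd: float = 0.5
    prep_log_sd: float = 0.2
    drift_pct_per_injection: float = 0.0
    is_nominal_uM: float = 5.0
    window_min: float = 0.45
    baseline_step: float = 0.045

    def __post_init__(self) -> None:
        if min(self.rt_step, self.peak_sigma_min, self.window_min) <= 0:
            raise ValueError("rt_step, peak_sigma_min and window_min must be positive")
        if min(self.mz_jitter_ppm, self.noise_sd, self.prep_log_sd) < 0:
            raise ValueError("noise SDs must be >= 0")

    def response_factors(self, panel: Panel) -> dict[str, float]:
        """Deterministic per-compound response factors (counts*min/uM).

        Drawn once from the seed so that calibration ladders and study
        runs built from the same spec share the same factors.
        """
        rng = np.random.default_rng([self.seed, 101])
        names = sorted(e.name for e in panel)
        draws = np.exp(rng.normal(0.0, self.response_factor_log_sd, len(names)))
        return {n: self.response_factor_mean * d for n, d in zip(names, draws)}


@dataclass(frozen=True)
class ScenarioSpec:
    """One study condition: a name and metabolite fold-change multipliers."""

    name: str
    fold_changes: dict[str, float] = field(default_factory=dict)
    n_replicates: int = 4

    def __post_init__(self) -> None:
        if self.n_replicates < 3:
            raise ValueError("need at least 3 replicates per condition")
        if any(f <= 0 for f in self.fold_changes.values()):
            raise ValueError("fold changes must be positive")


def default_scenarios(n_replicates: int = 4) -> list[ScenarioSpec]:
    """Control plus the five inhibitor conditions.

    Fold-change directions follow the reported inhibitor effects
    (glycolysis block, fatty-acid-oxidation block, complex-I inhibition,
    mitochondrial pyruvate-carrier block, succinate-dehydrogenase
    inhibition); magnitudes are illustrative simulation settings, not
    measured effect sizes.
    """
    mk = lambda name, fc: ScenarioSpec(name, fc, n_replicates)
    return [
        mk("control", {}),
        mk("2DG", {
            "Fumarate": 0.5, "Malate": 0.5,
            "Sedoheptulose-7-phosphate (SH7P)": 0.5,
            "Uridine diphosphate N-acetylglucosamine (UDP-GlcNAc)": 0.5,
            "Glucose": 3.0,
        }),
        mk("etomoxir", {
            "Fumarate": 2.0, "Malate": 2.0,
            "Nicotinamide adenine dinucleotide phosphate reduced (NADPH)": 2.0,
            "Creatine": 0.5,
        }),
        mk("rotenone", {
            "Fumarate": 1.8, "Malate": 1.8,
            "Uridine diphosphate N-acetylglucosamine (UDP-GlcNAc)": 1.8,
            "Uridine diphosphate-glucose (UDP-Glc)": 1.8,
        }),
        mk("UK-5099", {
            "Pyruvate": 3.0, "Malate": 1.8,
            "Nicotinamide adenine dinucleotide oxidized (NAD+)": 1.8,
            "Glucose-6-phosphate (G6P)": 0.5,
        }),
        mk("3-NPA", {
            "Succinate": 4.0, "Fumarate": 0.5, "Glutamate": 0.6,
            "Glutathione (GSH)": 0.6, "Glucose-6-phosphate (G6P)": 0.6,
        }),
    ]


DEFAULT_SCENARIOS = default_scenarios()


def _emit_compound(
    rng: np.random.Generator,
    spec: RunSpec,
    entry: PanelEntry,
    polarity: str,
    area: float,
    sensitivity: float,
    rows: list,
    sample_id: str,
    role: str,
) -> None:
    """Append one compound's peak + baseline centroids to ``rows``."""
    theo = entry.mz(polarity)
    if theo is None:
        return
    sigma = spec.peak_sigma_min
    rt0 = entry.rt_min
    grid = np.arange(rt0 - 3.5 * sigma, rt0 + 3.5 * sigma + spec.rt_step / 2, spec.rt_step)
    height = area / (sigma * _SQRT2PI)
    signal = height * np.exp(-0.5 * ((grid - rt0) / sigma) ** 2)
    base_lo = np.arange(rt0 - spec.window_min, grid[0], spec.baseline_step)
    base_hi = np.arange(grid[-1] + spec.baseline_step, rt0 + spec.window_min, spec.baseline_step)
    rts = np.concatenate([base_lo, grid, base_hi])
    sig = np.concatenate([np.zeros(len(base_lo)), signal, np.zeros(len(base_hi))])
    noise = rng.normal(0.0, spec.noise_sd, len(rts))
    inten = np.clip(sig * sensitivity + np.abs(noise) * (sig == 0) + noise * (sig > 0), 0.0, None)
    mzs = theo * (1.0 + rng.normal(0.0, spec.mz_jitter_ppm, len(rts)) * 1e-6)
    for rt, mz, it in zip(rts, mzs, inten):
        if it > 0:
            rows.append((sample_id, role, round(rt, 5), mz, it))


def simulate_ladder(
    panel: Panel,
    ladder: CalibrationLadder | None = None,
    spec: RunSpec = RunSpec(),
    polarity: str = "-",
) -> FeatureTable:
    """Calibration-standard runs: one injection per ladder level.

    Every analyte with an ion in ``polarity`` appears at the level's
    nominal concentration; peak area is response_factor x concentration
    (no preparation variability — standards come from one dilution
    series).  Sample role is ``standard`` with ``nominal_uM`` set.
    """
    if ladder is None:
        ladder = make_ladder()
    rfs = spec.response_factors(panel)
    rng = np.random.default_rng([spec.seed, 202])
    rows: list = []
    meta = []
    for li, conc in enumerate(ladder.levels):
        sid = f"std_L{li + 1}"
        meta.append((sid, "standard", li, ladder.labels[li], pd.NA))
        for entry in panel.analytes:
            _emit_compound(rng, spec, entry, polarity, rfs[entry.name] * conc,
                           1.0, rows, sid, "standard")
    data = pd.DataFrame(rows, columns=["sample_id", "role", "rt_min", "mz", "intensity"])
    samples = pd.DataFrame(
        meta, columns=["sample_id", "role", "order", "nominal_uM", "group"]
    ).set_index("sample_id")
    return FeatureTable(polarity, data, samples)


def simulate_study(
    panel: Panel,
    scenarios: list[ScenarioSpec] | None = None,
    spec: RunSpec = RunSpec(),
    polarity: str = "-",
    qc_every: int = 6,
) -> tuple[FeatureTable, pd.DataFrame]:
    """An inhibitor study run: replicated conditions, QCs, ground truth.

    Study injections are randomized in order; a pooled QC (the mean
    composition over all conditions) opens the sequence and recurs every
    ``qc_every`` study injections.  Internal standards are spiked at a
    constant nominal level into every injection; each sample carries a
    lognormal preparation scale factor applied to all its channels.

    Returns the feature table and a tidy ground-truth frame with one row
    per (sample, metabolite): true concentration and prep factor.
    """
    if scenarios is None:
        scenarios = default_scenarios()
    if not any(s.name == "control" for s in scenarios):
        raise ValueError("scenarios must include a control condition")
    rfs = spec.response_factors(panel)
    rng = np.random.default_rng([spec.seed, 303])

    analytes = [e for e in panel.analytes if e.mz(polarity) is not None]
    base = {
        e.name: float(np.clip(np.exp(rng.normal(math.log(2.0), 0.5)), 0.3, 10.0))
        for e in sorted(analytes, key=lambda e: e.name)
    }
    # study samples
    study: list[tuple[str, str, dict[str, float]]] = []
    for sc in scenarios:
        for rep in range(sc.n_replicates):
            sid = f"{sc.name}_r{rep + 1}"
            concs = {n: c * sc.fold_changes.get(n, 1.0) for n, c in base.items()}
            study.append((sid, sc.name, concs))
    order = rng.permutation(len(study))
    study = [study[i] for i in order]
    qc_concs = {
        n: float(np.mean([c * sc.fold_changes.get(n, 1.0)
                          for sc in scenarios for c in [base[n]]]))
        for n in base
    }
    # injection sequence: QC first, then a QC after every `qc_every` studies
    sequence: list[tuple[str, str, str, dict[str, float]]] = []
    qc_i = 1
    sequence.append((f"QC_{qc_i}", "QC", "QC", qc_concs))
    for i, (sid, group, concs) in enumerate(study, start=1):
        sequence.append((sid, "study", group, concs))
        if i % qc_every == 0 and i < len(study):
            qc_i += 1
            sequence.append((f"QC_{qc_i}", "QC", "QC", qc_concs))
    qc_i += 1
    sequence.append((f"QC_{qc_i}", "QC", "QC", qc_concs))

    rows: list = []
    meta = []
    truth = []
    for inj, (sid, role, group, concs) in enumerate(sequence):
        prep = float(np.exp(rng.normal(0.0, spec.prep_log_sd))) if spec.prep_log_sd else 1.0
        sens = prep * (1.0 + spec.drift_pct_per_injection / 100.0) ** inj
        meta.append((sid, role, inj, pd.NA, group))
        for entry in analytes:
            area = rfs[entry.name] * concs[entry.name]
            _emit_compound(rng, spec, entry, polarity, area, sens, rows, sid, role)
            truth.append((sid, role, group, inj, entry.name, concs[entry.name], prep))
        for ist in panel.internal_standards:
            if ist.mz(polarity) is None:
                continue
            area = rfs[ist.name] * spec.is_nominal_uM
            _emit_compound(rng, spec, ist, polarity, area, sens, rows, sid, role)
            truth.append((sid, role, group, inj, ist.name, spec.is_nominal_uM, prep))
    data = pd.DataFrame(rows, columns=["sample_id", "role", "rt_min", "mz", "intensity"])
    samples = pd.DataFrame(
        meta, columns=["sample_id", "role", "order", "nominal_uM", "group"]
    ).set_index("sample_id")
    truth_df = pd.DataFrame(
        truth,
        columns=["sample_id", "role", "group", "injection", "metabolite",
                 "true_uM", "prep_factor"],
    )
    return FeatureTable(polarity, data, samples), truth_df
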