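"""Synthetic-data generators for the screen and the downstream assays.

The array simulator emulates the study design the pipeline assumes: four
breast cancer cell lines (two HER2-positive, two HER2-negative), each profiled
once with and once without trastuzumab (4 ug/ml, 144 h) — eight arrays, no
replicates — with log-normal linear intensities (noise additive in log2) and
treatment effects planted only where the configuration says so.  A ground
truth table accompanies every simulated dataset so recovery can be scored.

The assay simulators produce the measurement shapes the statistics in
:mod:`trzmir.assays` consume: Cq tables, WST-1 absorbances, DNA-content
histograms, Annexin-V event intensities, and firefly/renilla pairs.

All randomness flows from one integer seed per call; each assay draws from
its own deterministic child stream, so adding one simulator call never shifts
another's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assays import CellCycleHistogram, CqMeasurement, LuciferaseMeasurement, ViabilityMeasurement
from .errors import ConfigError
from .screen import CONTROL, TREATED, IntensityMatrix, SampleMeta

DEFAULT_LINES = (
    ("SKBR3", "positive"),
    ("BT474", "positive"),
    ("MCF7", "negative"),
    ("MDA-MB-231", "negative"),
)

DEFAULT_DOSE_UG_ML = 4.0
DEFAULT_HOURS = 144.0


def _child_rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-assay stream derived from one global seed."""
    ss = np.random.SeedSequence([seed, zlib.crc32(stream.encode())])
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# Array simulation
# ---------------------------------------------------------------------------


@dataclass
class ArraySimConfig:
    """Configuration of the synthetic two-factor array experiment.

    ``planted`` maps miRNA name -> {cell line -> log2 treatment effect};
    unlisted combinations have effect 0 (non-responders).
    """

    n_mirnas: int = 200
    lines: tuple = DEFAULT_LINES
    baseline_log2_mean: float = 9.0
    baseline_log2_sd: float = 1.5
    noise_log2_sd: float = 0.1
    planted: dict = field(default_factory=dict)
    low_expression_fraction: float = 0.3
    replicates: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirnas <= 0:
            raise ConfigError("n_mirnas must be positive")
        if not self.lines:
            raise ConfigError("at least one cell line required")
        if self.baseline_log2_sd < 0 or self.noise_log2_sd < 0:
            raise ConfigError("standard deviations must be nonnegative")
        if not 0.0 <= self.low_expression_fraction <= 1.0:
            raise ConfigError("low_expression_fraction must lie in [0, 1]")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        line_names = {name for name, _ in self.lines}
        for mirna, effects in self.planted.items():
            unknown = set(effects) - line_names
            if unknown:
                raise ConfigError(f"planted effect for {mirna!r} names unknown lines {unknown}")
            for eff in effects.values():
                if not np.isfinite(eff):
                    raise ConfigError("planted effects must be finite")


def mirna_names(n: int) -> list[str]:
    return [f"miR-sim-{i:04d}" for i in range(n)]


def simulate_array(config: ArraySimConfig) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Simulate the 8-sample array experiment; return matrix plus ground truth.

    Linear intensity = 2 ** (baseline + effect * treated + N(0, noise_sd)).
    A ``low_expression_fraction`` of miRNAs receives baselines below the log2
    expression floor of 6 in all samples; planted responders are never drawn
    from that subset (an effect on an unexpressed probe is unmeasurable).
    The truth table has one row per (miRNA, line) with the true log2 effect
    and the per-miRNA expressed flag.
    """
    names = mirna_names(config.n_mirnas)
    unknown = set(config.planted) - set(names)
    if unknown:
        raise ConfigError(f"planted effects name unknown miRNAs {sorted(unknown)}")
    rng = _child_rng(config.rng_seed, "array")

    n = config.n_mirnas
    baselines = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    baselines = np.maximum(baselines, 6.5)  # expressed probes sit above the floor

    n_low = int(round(config.low_expression_fraction * n))
    plantable = [i for i, name in enumerate(names) if name not in config.planted]
    n_low = min(n_low, len(plantable))
    low_idx = rng.choice(plantable, size=n_low, replace=False) if n_low else np.array([], int)
    baselines[low_idx] = rng.uniform(2.0, 5.0, size=n_low)
    expressed = np.ones(n, dtype=bool)
    expressed[low_idx] = False

    samples: list[SampleMeta] = []
    columns: dict[str, np.ndarray] = {}
    truth_rows = []
    for line, status in config.lines:
        effects = np.array(
            [config.planted.get(name, {}).get(line, 0.0) for name in names], dtype=float
        )
        for name, eff in zip(names, effects):
            truth_rows.append(
                {"mirna_id": name, "cell_line": line, "true_log2_effect": float(eff)}
            )
        for treatment in (TREATED, CONTROL):
            for rep in range(config.replicates):
                suffix = f"_r{rep + 1}" if config.replicates > 1 else ""
                sid = f"{line}_{treatment}{suffix}"
                noise = (
                    rng.normal(0.0, config.noise_log2_sd, size=n)
                    if config.noise_log2_sd > 0
                    else np.zeros(n)
                )
                log2_signal = baselines + (effects if treatment == TREATED else 0.0) + noise
                columns[sid] = 2.0 ** log2_signal
                samples.append(
                    SampleMeta(
                        sample_id=sid,
                        cell_line=line,
                        her2_status=status,
                        treatment=treatment,
                        dose_ug_ml=DEFAULT_DOSE_UG_ML if treatment == TREATED else 0.0,
                        hours=DEFAULT_HOURS,
                    )
                )

    values = pd.DataFrame(columns, index=pd.Index(names, name="mirna_id"))
    truth = pd.DataFrame(truth_rows)
    truth["expressed"] = truth["mirna_id"].map(dict(zip(names, expressed)))
    return IntensityMatrix(values=values, samples=samples), truth


def write_array_dataset(
    matrix: IntensityMatrix, truth: pd.DataFrame, outdir
) -> dict[str, Path]:
    """Write expression TSV, sample sheet CSV and truth TSV; return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "expression.tsv",
        "samples": outdir / "samples.csv",
        "truth": outdir / "truth.tsv",
    }
    matrix.values.to_csv(paths["matrix"], sep="\t", float_format="%.6f")
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "cell_line": s.cell_line,
                "her2_status": s.her2_status,
                "treatment": s.treatment,
                "dose_ug_ml": s.dose_ug_ml,
                "hours": s.hours,
            }
            for s in matrix.samples
        ]
    ).to_csv(paths["samples"], index=False)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Assay simulation
# ---------------------------------------------------------------------------


@dataclass
class AssaySimConfig:
    """Ground-truth parameters for the downstream assay simulators."""

    luciferase_true_repression: float = 0.27
    luciferase_cv: float = 0.05
    replicates: int = 3
    cellcycle_true_fractions: tuple = (0.60, 0.30, 0.10)  # (G1, S, G2/M)
    cellcycle_events: int = 10_000
    viability_true_inhibition: float = 0.40
    apoptosis_true_fraction: float = 0.147
    rng_seed: int = 0
    # measurement-scale defaults
    qpcr_true_ratio: float = 4.0
    qpcr_noise_sd: float = 0.0
    qpcr_base_cq: float = 24.0
    qpcr_ref_cq: float = 20.0
    viability_cv: float = 0.03
    apoptosis_events: int = 10_000
    dna_g1_mean: float = 100.0
    dna_cv: float = 0.03
    g2_broadening: float = 1.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.luciferase_true_repression < 1.0:
            raise ConfigError("luciferase_true_repression must lie in [0, 1)")
        if self.luciferase_cv < 0 or self.viability_cv < 0 or self.qpcr_noise_sd < 0:
            raise ConfigError("noise levels must be nonnegative")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        fr = np.asarray(self.cellcycle_true_fractions, dtype=float)
        if fr.shape != (3,) or (fr < 0).any() or (fr > 1).any():
            raise ConfigError("cell-cycle fractions must be three values in [0, 1]")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ConfigError("cell-cycle fractions must sum to 1")
        if self.cellcycle_events < 1:
            raise ConfigError("cellcycle_events must be positive")
        if not 0.0 <= self.viability_true_inhibition < 1.0:
            raise ConfigError("viability_true_inhibition must lie in [0, 1)")
        if not 0.0 <= self.apoptosis_true_fraction <= 1.0:
            raise ConfigError("apoptosis_true_fraction must lie in [0, 1]")


def _mult_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


DEFAULT_CONSTRUCTS = ("wt", "mut1", "mut2", "mut1+2", "empty")


def _construct_repression(construct: str, r: float) -> float:
    """Expected repression per construct: two seed sites act multiplicatively,
    each contributing sqrt(1 - r); mutating a site removes its contribution."""
    per_site = np.sqrt(1.0 - r)
    surviving = {"wt": 2, "mut1": 1, "mut2": 1, "mut1+2": 0, "empty": 0}.get(construct, 0)
    return float(1.0 - per_site**surviving)


def simulate_luciferase(
    config: AssaySimConfig, constructs=DEFAULT_CONSTRUCTS
) -> list[LuciferaseMeasurement]:
    """Firefly/renilla replicate pairs per construct x {ncRNA, mirna} oligo."""
    rng = _child_rng(config.rng_seed, "luciferase")
    firefly_base, renilla_base = 2.0e5, 1.0e5
    out = []
    for construct in constructs:
        repression = _construct_repression(construct, config.luciferase_true_repression)
        for oligo, factor in (("ncRNA", 1.0), ("mirna", 1.0 - repression)):
            ff_noise = _mult_noise(rng, config.luciferase_cv, config.replicates)
            rn_noise = _mult_noise(rng, config.luciferase_cv, config.replicates)
            for k in range(config.replicates):
                out.append(
                    LuciferaseMeasurement(
                        construct=construct,
                        oligo=oligo,
                        firefly=firefly_base * factor * ff_noise[k],
                        renilla=renilla_base * rn_noise[k],
                    )
                )
    return out


def simulate_cell_cycle(config: AssaySimConfig) -> CellCycleHistogram:
    """Draw DNA-content events from the three-component mixture and bin them.

    G1 ~ N(mu, sigma); G2/M ~ N(2mu, sigma * g2_broadening);
    S ~ uniform(mu, 2mu) + N(0, sigma).
    """
    rng = _child_rng(config.rng_seed, "cellcycle")
    mu = config.dna_g1_mean
    sigma = config.dna_cv * mu
    n = config.cellcycle_events
    counts = rng.multinomial(n, np.asarray(config.cellcycle_true_fractions, float))
    g1 = rng.normal(mu, sigma, counts[0])
    s = rng.uniform(mu, 2 * mu, counts[1]) + rng.normal(0.0, sigma, counts[1])
    g2m = rng.normal(2 * mu, sigma * config.g2_broadening, counts[2])
    events = np.concatenate([g1, s, g2m])
    edges = np.linspace(0.0, 3.0 * mu, 257)
    hist, _ = np.histogram(events, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return CellCycleHistogram(bin_centers=centers, counts=hist)


@dataclass
class AssayPanel:
    """One simulated bundle of qPCR, viability and apoptosis raw data."""

    cq_sample: CqMeasurement
    cq_calibrator: CqMeasurement
    viability_treated: ViabilityMeasurement
    viability_control: ViabilityMeasurement
    annexin_intensities: np.ndarray
    annexin_threshold: float


def simulate_assay_panel(config: AssaySimConfig) -> AssayPanel:
    """Simulate the qPCR, WST-1 and Annexin-V raw measurements.

    Cq = base - log2(true relative quantity) + N(0, qpcr_noise_sd); treated
    absorbances are scaled by (1 - viability_true_inhibition); Annexin event
    positivity is Bernoulli(apoptosis_true_fraction) with well-separated
    log-normal intensity modes around 10 (negative) and 1000 (positive).
    """
    rng = _child_rng(config.rng_seed, "panel")
    reps = config.replicates

    def cq_noise(size):
        if config.qpcr_noise_sd == 0:
            return np.zeros(size)
        return rng.normal(0.0, config.qpcr_noise_sd, size)

    cq_sample = CqMeasurement(
        sample_id="sample",
        target="target",
        references=["ref"],
        cq_target=list(config.qpcr_base_cq - np.log2(config.qpcr_true_ratio) + cq_noise(reps)),
        cq_refs={"ref": list(config.qpcr_ref_cq + cq_noise(reps))},
    )
    cq_calibrator = CqMeasurement(
        sample_id="calibrator",
        target="target",
        references=["ref"],
        cq_target=list(config.qpcr_base_cq + cq_noise(reps)),
        cq_refs={"ref": list(config.qpcr_ref_cq + cq_noise(reps))},
    )

    a450_base = 1.0
    viability_control = ViabilityMeasurement(
        condition="control",
        dose_ug_ml=0.0,
        a450=list(a450_base * _mult_noise(rng, config.viability_cv, reps)),
    )
    viability_treated = ViabilityMeasurement(
        condition="treated",
        dose_ug_ml=DEFAULT_DOSE_UG_ML,
        a450=list(
            a450_base
            * (1.0 - config.viability_true_inhibition)
            * _mult_noise(rng, config.viability_cv, reps)
        ),
    )

    n_ev = config.apoptosis_events
    positive = rng.random(n_ev) < config.apoptosis_true_fraction
    intensities = np.where(
        positive,
        rng.lognormal(np.log(1000.0), 0.3, n_ev),
        rng.lognormal(np.log(10.0), 0.3, n_ev),
    )
    return AssayPanel(
        cq_sample=cq_sample,
        cq_calibrator=cq_calibrator,
        viability_treated=viability_treated,
        viability_control=viability_control,
        annexin_intensities=intensities,
        annexin_threshold=100.0,
    )


# ---------------------------------------------------------------------------
# Assay CSV writers (round-trip with the readers in trzmir.assays)
# ---------------------------------------------------------------------------


def write_assay_dataset(
    panel: AssayPanel,
    luciferase: list[LuciferaseMeasurement],
    histogram: CellCycleHistogram,
    outdir,
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cq": outdir / "cq.csv",
        "viability": outdir / "viability.csv",
        "cellcycle": outdir / "cellcycle.csv",
        "annexin": outdir / "annexin.csv",
        "luciferase": outdir / "luciferase.csv",
    }
    cq_rows = []
    for meas in (panel.cq_sample, panel.cq_calibrator):
        for k, cq in enumerate(meas.cq_target, 1):
            cq_rows.append(
                {"sample_id": meas.sample_id, "gene": meas.target, "is_reference": False,
                 "replicate": k, "cq": cq}
            )
        for ref in meas.references:
            for k, cq in enumerate(meas.cq_refs[ref], 1):
                cq_rows.append(
                    {"sample_id": meas.sample_id, "gene": ref, "is_reference": True,
                     "replicate": k, "cq": cq}
                )
    pd.DataFrame(cq_rows).to_csv(paths["cq"], index=False)

    via_rows = []
    for meas in (panel.viability_control, panel.viability_treated):
        for k, a in enumerate(meas.a450, 1):
            via_rows.append(
                {"condition": meas.condition, "dose_ug_ml": meas.dose_ug_ml,
                 "replicate": k, "a450": a}
            )
    pd.DataFrame(via_rows).to_csv(paths["viability"], index=False)

    pd.DataFrame(
        {"bin_center": histogram.bin_centers, "count": histogram.counts}
    ).to_csv(paths["cellcycle"], index=False)

    pd.DataFrame(
        {"event": np.arange(1, panel.annexin_intensities.size + 1),
         "intensity": panel.annexin_intensities}
    ).to_csv(paths["annexin"], index=False)

    luc_rows = []
    rep_counter: dict[tuple, int] = {}
    for m in luciferase:
        key = (m.construct, m.oligo)
        rep_counter[key] = rep_counter.get(key, 0) + 1
        luc_rows.append(
            {"construct": m.construct, "oligo": m.oligo, "replicate": rep_counter[key],
             "firefly": m.firefly, "renilla": m.renilla}
        )
    pd.DataFrame(luc_rows).to_csv(paths["luciferase"], index=False)
    return paths
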