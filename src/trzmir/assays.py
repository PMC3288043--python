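"""Downstream assay statistics.

Quantitative follow-up of the array screen: relative quantification from PCR
quantification cycles (delta-delta-Cq), WST-1 viability inhibition, DNA-content
(propidium iodide) cell-cycle fraction fitting, Annexin-V apoptosis fractions,
dual-luciferase repression, and the unpaired pooled-variance Student t-test
used for all group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigError, ContractError, DesignError

# ---------------------------------------------------------------------------
# qPCR relative quantification
# ---------------------------------------------------------------------------


@dataclass
class CqMeasurement:
    """Replicate quantification cycles for a target and its reference genes."""

    sample_id: str
    target: str
    references: list[str]
    cq_target: list[float]
    cq_refs: dict[str, list[float]]

    def __post_init__(self) -> None:
        if not self.cq_target:
            raise ContractError("cq_target needs at least one replicate")
        for ref in self.references:
            if not self.cq_refs.get(ref):
                raise ContractError(f"missing replicates for reference {ref!r}")
        vals = [*self.cq_target, *(v for r in self.references for v in self.cq_refs[r])]
        if not np.all(np.isfinite(vals)):
            raise ContractError("non-finite Cq value")

    def delta_cq(self) -> float:
        """Mean target Cq minus the mean of the per-reference mean Cqs.

        Averaging reference Cq means arithmetically corresponds to the
        geometric mean of the reference quantities.
        """
        ref_means = [float(np.mean(self.cq_refs[r])) for r in self.references]
        return float(np.mean(self.cq_target)) - float(np.mean(ref_means))


@dataclass(frozen=True)
class RelativeQuantity:
    sample_id: str
    quantity_ratio: float
    calibrator_id: str


def delta_delta_cq(
    sample: CqMeasurement, calibrator: CqMeasurement, efficiency: float = 2.0
) -> RelativeQuantity:
    """Quantity of the target in ``sample`` relative to ``calibrator``.

    ratio = efficiency ** -(dCq_sample - dCq_calibrator).  The amplification
    efficiency defaults to the ideal doubling per cycle.
    """
    if sample.target != calibrator.target or sorted(sample.references) != sorted(
        calibrator.references
    ):
        raise ContractError("sample and calibrator must share target and references")
    if efficiency <= 1.0:
        raise ConfigError("amplification efficiency must exceed 1")
    ddcq = sample.delta_cq() - calibrator.delta_cq()
    return RelativeQuantity(
        sample_id=sample.sample_id,
        quantity_ratio=float(efficiency ** (-ddcq)),
        calibrator_id=calibrator.sample_id,
    )


# ---------------------------------------------------------------------------
# WST-1 viability
# ---------------------------------------------------------------------------


@dataclass
class ViabilityMeasurement:
    condition: str
    dose_ug_ml: float
    a450: list[float]

    def __post_init__(self) -> None:
        if not self.a450 or min(self.a450) <= 0:
            raise ConfigError("A450 replicates must be positive")

    @property
    def mean(self) -> float:
        return float(np.mean(self.a450))


def viability_inhibition(
    treated: ViabilityMeasurement, control: ViabilityMeasurement
) -> tuple[float, float]:
    """Treated/control absorbance ratio and percent growth inhibition.

    Replicate absorbances are averaged before the ratio is formed.
    """
    ratio = treated.mean / control.mean
    return float(ratio), float(100.0 * (1.0 - ratio))


def mean_inhibition(percent_inhibitions) -> float:
    """Cross-line summary: arithmetic mean of per-line inhibition percentages."""
    arr = np.asarray(list(percent_inhibitions), dtype=float)
    if arr.size == 0:
        raise ConfigError("mean_inhibition of an empty list")
    return float(arr.mean())


# ---------------------------------------------------------------------------
# Cell-cycle histogram fitting
# ---------------------------------------------------------------------------


@dataclass
class CellCycleHistogram:
    """DNA-content histogram (PI fluorescence) as bin centers and counts."""

    bin_centers: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.bin_centers.shape != self.counts.shape:
            raise ConfigError("bin_centers and counts must have matching shapes")
        if (self.counts < 0).any():
            raise ConfigError("negative bin count")
        if self.counts.sum() <= 0:
            raise ConfigError("histogram has no events")

    @property
    def n_events(self) -> int:
        return int(self.counts.sum())


@dataclass
class CellCycleFractions:
    g1: float
    s: float
    g2m: float
    g1_mean: float = float("nan")
    g1_sd: float = float("nan")
    g2_broadening: float = float("nan")
    neg_loglik: float = float("nan")

    def __post_init__(self) -> None:
        total = self.g1 + self.s + self.g2m
        if abs(total - 1.0) > 1e-6:
            raise ConfigError(f"fractions sum to {total}, not 1")


def _cellcycle_density(x: np.ndarray, mu: float, sigma: float, broadening: float,
                       w: np.ndarray) -> np.ndarray:
    """Mixture density: G1 ~ N(mu, sigma), G2/M ~ N(2mu, sigma*broadening),
    S ~ uniform(mu, 2mu) convolved with N(0, sigma)."""
    g1 = stats.norm.pdf(x, mu, sigma)
    g2m = stats.norm.pdf(x, 2.0 * mu, sigma * broadening)
    s = (stats.norm.cdf((x - mu) / sigma) - stats.norm.cdf((x - 2.0 * mu) / sigma)) / mu
    return w[0] * g1 + w[1] * s + w[2] * g2m


def _softmax3(a: float, b: float) -> np.ndarray:
    z = np.array([a, b, 0.0])
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def fit_cell_cycle(hist: CellCycleHistogram) -> CellCycleFractions:
    """Maximum-likelihood G1/S/G2-M fractions from a DNA-content histogram.

    Fits a three-component mixture by multinomial likelihood over bins: a
    Gaussian G1 peak at mu, a Gaussian G2/M peak constrained to 2*mu, and a
    Gaussian-smoothed uniform S-phase bridge between them.  mu, the G1 CV,
    the G2/M broadening factor and the mixing weights are all estimated.
    """
    if hist.n_events < 100:
        raise ConfigError("need at least 100 events for a stable fit")
    if np.count_nonzero(hist.counts) < 2:
        raise ConfigError("degenerate histogram: all events in one bin")
    x = hist.bin_centers
    counts = np.asarray(hist.counts, dtype=float)

    # init: G1 at the histogram mode, CV 5%
    mu0 = float(x[np.argmax(counts)])
    mu0 = max(mu0, 1e-6)
    sigma0 = 0.05 * mu0

    def nll(theta: np.ndarray) -> float:
        mu, log_sigma, log_broad, a, b = theta
        if mu <= 0:
            return 1e12
        sigma = np.exp(log_sigma)
        broad = np.exp(log_broad)
        w = _softmax3(a, b)
        dens = _cellcycle_density(x, mu, sigma, broad, w)
        dens = np.clip(dens, 1e-300, None)
        p = dens / dens.sum()
        return -float(np.sum(counts * np.log(p)))

    candidates = []
    # two starts: the histogram mode could be the G1 or (rarely) the G2/M peak
    for mu_start in (mu0, mu0 / 2.0):
        if mu_start <= 0:
            continue
        theta0 = np.array([mu_start, np.log(0.05 * mu_start), 0.0, 0.5, -0.5])
        res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        candidates.append(res)
    # a unimodal histogram fits equally well as "all G1 at mu" or "all G2/M at
    # mu/2"; among statistically indistinguishable optima anchor G1 at the
    # observed peak (the larger G1 weight), the usual convention
    best_fun = min(res.fun for res in candidates)
    near = [res for res in candidates if res.fun <= best_fun + 2.0]
    best = max(near, key=lambda res: _softmax3(res.x[3], res.x[4])[0])
    mu, log_sigma, log_broad, a, b = best.x
    w = _softmax3(a, b)
    return CellCycleFractions(
        g1=float(w[0]), s=float(w[1]), g2m=float(w[2]),
        g1_mean=float(mu), g1_sd=float(np.exp(log_sigma)),
        g2_broadening=float(np.exp(log_broad)), neg_loglik=float(best.fun),
    )


# ---------------------------------------------------------------------------
# Annexin-V apoptosis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ApoptosisResult:
    positive_fraction: float
    n_events: int
    threshold: float


def annexin_fraction(intensities, threshold: float) -> ApoptosisResult:
    """Fraction of events whose Annexin-V intensity exceeds the gate."""
    arr = np.asarray(list(intensities), dtype=float)
    if arr.size == 0:
        raise ConfigError("no flow events")
    positives = int((arr > threshold).sum())
    return ApoptosisResult(
        positive_fraction=positives / arr.size, n_events=int(arr.size), threshold=float(threshold)
    )


# ---------------------------------------------------------------------------
# Dual-luciferase repression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LuciferaseMeasurement:
    construct: str  # wt | mut1 | mut2 | mut1+2 | empty
    oligo: str  # ncRNA | mirna | inhibitor | none
    firefly: float
    renilla: float

    def __post_init__(self) -> None:
        if self.firefly <= 0 or self.renilla <= 0:
            raise ConfigError("luminescence must be positive")

    @property
    def normalized(self) -> float:
        return self.firefly / self.renilla


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_two_sided: float
    zero_variance: bool = False


@dataclass(frozen=True)
class RepressionEstimate:
    percent_repression: float
    p_value: float
    n_oligo: int
    n_reference: int


def unpaired_t_test(a, b) -> TTestResult:
    """Unpaired pooled-variance Student t-test, two-sided.

    df = n_a + n_b - 2.  With zero pooled variance the statistic degenerates:
    equal means give t = 0, p = 1; unequal means give the p -> 0 limit,
    flagged via ``zero_variance``.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ContractError("each group needs at least two observations")
    na, nb = a.size, b.size
    df = na + nb - 2
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if pooled_var == 0.0:
        if diff == 0.0:
            return TTestResult(t=0.0, df=float(df), p_two_sided=1.0, zero_variance=True)
        return TTestResult(t=float(np.sign(diff)) * np.inf, df=float(df), p_two_sided=0.0,
                           zero_variance=True)
    se = np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p_two_sided=float(p))


def luciferase_repression(
    measurements: list[LuciferaseMeasurement],
    construct: str,
    oligo: str,
    reference_oligo: str = "ncRNA",
) -> RepressionEstimate:
    """Percent repression of a reporter construct by a miRNA oligo.

    Firefly is normalized to renilla per replicate; repression is
    100 * (1 - mean(oligo) / mean(reference)).  The p-value is the unpaired
    Student t-test on the normalized activities (NaN when a group has fewer
    than two replicates).
    """
    grp = [m.normalized for m in measurements if m.construct == construct and m.oligo == oligo]
    ref = [
        m.normalized
        for m in measurements
        if m.construct == construct and m.oligo == reference_oligo
    ]
    if not ref:
        raise ContractError(f"no reference ({reference_oligo!r}) replicates for {construct!r}")
    if not grp:
        raise ContractError(f"no {oligo!r} replicates for {construct!r}")
    percent = 100.0 * (1.0 - float(np.mean(grp)) / float(np.mean(ref)))
    if len(grp) >= 2 and len(ref) >= 2:
        p = unpaired_t_test(grp, ref).p_two_sided
    else:
        p = float("nan")
    return RepressionEstimate(
        percent_repression=float(percent), p_value=p, n_oligo=len(grp), n_reference=len(ref)
    )


# ---------------------------------------------------------------------------
# CSV readers (dialects written by trzmir.simulate)
# ---------------------------------------------------------------------------


def read_cq_csv(path) -> list[CqMeasurement]:
    """Long-format Cq table: sample_id,gene,is_reference,replicate,cq."""
    df = pd.read_csv(path)
    out = []
    for sample_id, sub in df.groupby("sample_id", sort=False):
        refs = sorted(sub.loc[sub["is_reference"].astype(bool), "gene"].unique())
        targets = sub.loc[~sub["is_reference"].astype(bool), "gene"].unique()
        if len(targets) != 1:
            raise ContractError(f"sample {sample_id!r} must have exactly one target gene")
        target = targets[0]
        out.append(
            CqMeasurement(
                sample_id=str(sample_id),
                target=str(target),
                references=[str(r) for r in refs],
                cq_target=sub.loc[sub["gene"] == target, "cq"].astype(float).tolist(),
                cq_refs={
                    str(r): sub.loc[sub["gene"] == r, "cq"].astype(float).tolist() for r in refs
                },
            )
        )
    return out


def read_viability_csv(path) -> list[ViabilityMeasurement]:
    """Table: condition,dose_ug_ml,replicate,a450."""
    df = pd.read_csv(path)
    out = []
    for (condition, dose), sub in df.groupby(["condition", "dose_ug_ml"], sort=False):
        out.append(
            ViabilityMeasurement(
                condition=str(condition),
                dose_ug_ml=float(dose),
                a450=sub["a450"].astype(float).tolist(),
            )
        )
    return out


def read_histogram_csv(path) -> CellCycleHistogram:
    """Table: bin_center,count."""
    df = pd.read_csv(path)
    return CellCycleHistogram(
        bin_centers=df["bin_center"].to_numpy(float), counts=df["count"].to_numpy(int)
    )


def read_annexin_csv(path) -> np.ndarray:
    """Table: event,intensity -> intensity array."""
    df = pd.read_csv(path)
    return df["intensity"].to_numpy(float)


def read_luciferase_csv(path) -> list[LuciferaseMeasurement]:
    """Table: construct,oligo,replicate,firefly,renilla."""
    df = pd.read_csv(path)
    return [
        LuciferaseMeasurement(
            construct=str(r["construct"]),
            oligo=str(r["oligo"]),
            firefly=float(r["firefly"]),
            renilla=float(r["renilla"]),
        )
        for _, r in df.iterrows()
    ]
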