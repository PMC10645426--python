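"""Relative binding energies and additive energy-PWM models.

For an equilibrium P + S_i <=> P.S_i competed across a library, the ratio of
a variant's bound/unbound counts is proportional to its association
constant, so relative affinities follow from sequencing counts alone — the
free protein concentration cancels.  The relative binding energy of variant
x against the reference (consensus) sequence is the natural log of the
affinity ratio, in kT:

    ddG(x) = ln[(N_B(ref)/N_U(ref)) / (N_B(x)/N_U(x))]

The reference is 0 by definition and weaker binders are positive.  An
additive energy model (ePWM) assigns each variable position/base an energy
contribution; it is fit by least squares on variants within a small Hamming
neighborhood of the consensus, with the consensus base of every position
pinned to 0 and no intercept, so the model predicts exactly 0 at the
reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .library_design import (
    BASES,
    MembershipError,
    SpecseqLibrary,
    hamming_neighborhood,
)
from .read_processing import FractionCounts

#: kT in kcal/mol at 25 degC (Boltzmann k x 298.15 K); exposed for unit conversion
KCAL_PER_KT = 0.593


class AnchorError(ValueError):
    """The reference variant cannot anchor the table (fails min_reads)."""


class InsufficientOverlapError(ValueError):
    """Too few shared variants for a comparison or fit."""


@dataclass
class EnergyTable:
    """Per-variant relative binding energies (kT), anchored at a reference.

    ``energies`` maps every library variant to ddG in kT; variants failing
    the ``min_reads`` floor in either fraction are NaN (missing, not zero).
    """

    library: SpecseqLibrary
    reference_variant: str
    energies: dict[str, float]
    pseudocount: float
    min_reads: float
    counts: dict[str, tuple[float, float]] | None = None

    @property
    def n_used(self) -> int:
        return sum(1 for e in self.energies.values() if math.isfinite(e))

    def measured(self) -> dict[str, float]:
        """Only the variants with a finite energy."""
        return {v: e for v, e in self.energies.items() if math.isfinite(e)}

    def to_frame(self, units: str = "kT") -> pd.DataFrame:
        """Table sorted by variant: variant, ddG, n_bound, n_unbound, measured."""
        scale = {"kT": 1.0, "kcal/mol": KCAL_PER_KT}[units]
        rows = []
        for v in self.library.variants:
            nb, nu = (self.counts or {}).get(v, (np.nan, np.nan))
            e = self.energies[v]
            rows.append((v, e * scale if math.isfinite(e) else np.nan, nb, nu,
                         math.isfinite(e)))
        return pd.DataFrame(
            rows, columns=["variant", "ddG", "n_bound", "n_unbound", "measured"]
        )


def relative_energies(
    fc: FractionCounts,
    reference_variant: str,
    pseudocount: float = 1.0,
    min_reads: float = 10,
) -> EnergyTable:
    """Estimate per-variant ddG (kT) from fraction counts.

    ddG(x) = ln[(N_B(ref)+a)/(N_U(ref)+a)] - ln[(N_B(x)+a)/(N_U(x)+a)]
    with pseudocount ``a`` added to all four counts.  Variants with fewer
    than ``min_reads`` raw reads in either fraction are reported missing.
    The reference must pass the floor — there is no anchor without it.
    """
    reference_variant = reference_variant.upper()
    if reference_variant not in fc.library.variant_set:
        raise MembershipError(f"{reference_variant!r} is not a library variant")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    nb_ref, nu_ref = fc.counts[reference_variant]
    if nb_ref < min_reads or nu_ref < min_reads:
        raise AnchorError(
            f"reference {reference_variant} has counts ({nb_ref}, {nu_ref}) "
            f"below min_reads={min_reads}; cannot anchor the energy scale"
        )
    a = pseudocount
    if a == 0 and (nb_ref == 0 or nu_ref == 0):
        raise AnchorError("zero reference count with zero pseudocount")
    log_odds_ref = math.log((nb_ref + a) / (nu_ref + a))
    energies: dict[str, float] = {}
    for v in fc.library.variants:
        nb, nu = fc.counts[v]
        if nb < min_reads or nu < min_reads or (a == 0 and (nb == 0 or nu == 0)):
            energies[v] = float("nan")
            continue
        energies[v] = log_odds_ref - math.log((nb + a) / (nu + a))
    energies[reference_variant] = 0.0  # exact by definition
    return EnergyTable(
        library=fc.library,
        reference_variant=reference_variant,
        energies=energies,
        pseudocount=pseudocount,
        min_reads=min_reads,
        counts=dict(fc.counts),
    )


class FitStats(NamedTuple):
    r_squared: float
    residual_sd: float
    n_variants_fit: int


@dataclass
class EnergyPWM:
    """Additive position x base energy model over the variable positions.

    ``beta[(pos, base)]`` is the energy cost (kT) of carrying ``base`` at
    0-based core position ``pos`` relative to the reference base there, which
    is pinned to 0.  A base never observed in the fitted neighborhood has a
    NaN coefficient (missing, never extrapolated).
    """

    library: SpecseqLibrary
    reference_variant: str
    beta: dict[tuple[int, str], float]
    fit: FitStats
    max_mismatch: int = 2

    @property
    def variable_positions(self) -> tuple[int, ...]:
        return self.library.variable_positions

    def to_frame(self) -> pd.DataFrame:
        """position (1-based) x base matrix of energy contributions."""
        rows = []
        for p in self.variable_positions:
            rows.append([p + 1] + [self.beta[(p, b)] for b in BASES])
        return pd.DataFrame(rows, columns=["position", *BASES])


def fit_epwm(
    et: EnergyTable, max_mismatch: int = 2
) -> EnergyPWM:
    """Least-squares fit of an additive energy model on a mismatch neighborhood.

    Only variants within ``max_mismatch`` of the reference (and with a
    measured energy) enter the fit.  Encoding is reference-baseline one-hot
    with no intercept: the coefficient of the reference base at each
    position is fixed at 0, so the fitted model predicts exactly 0 for the
    reference.  Bases absent from the neighborhood design are reported NaN.
    """
    lib = et.library
    ref = et.reference_variant
    hood = hamming_neighborhood(ref, lib, max_mismatch)
    usable = sorted(set(et.measured()) & hood.members)
    varpos = lib.variable_positions
    columns = [(p, b) for p in varpos for b in BASES if b != ref[p]]
    col_index = {c: i for i, c in enumerate(columns)}
    X = np.zeros((len(usable), len(columns)))
    y = np.empty(len(usable))
    for i, v in enumerate(usable):
        y[i] = et.energies[v]
        for p in varpos:
            if v[p] != ref[p]:
                X[i, col_index[(p, v[p])]] = 1.0
    observed = X.any(axis=0)
    n_free = int(observed.sum())
    if len(usable) < max(n_free, 1):
        raise InsufficientOverlapError(
            f"{len(usable)} usable variants for {n_free} free coefficients"
        )
    coef = np.full(len(columns), np.nan)
    if n_free:
        sol, *_ = np.linalg.lstsq(X[:, observed], y, rcond=None)
        coef[observed] = sol
    pred = X[:, observed] @ coef[observed] if n_free else np.zeros(len(usable))
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum(y**2))  # uncentered: the model is anchored at 0
    dof = len(usable) - n_free
    residual_sd = math.sqrt(ss_res / dof) if dof > 0 else 0.0
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    beta = {(p, ref[p]): 0.0 for p in varpos}
    for c, value in zip(columns, coef):
        beta[c] = float(value)
    return EnergyPWM(
        library=lib,
        reference_variant=ref,
        beta=beta,
        fit=FitStats(r_squared=r_squared, residual_sd=residual_sd,
                     n_variants_fit=len(usable)),
        max_mismatch=max_mismatch,
    )


def predict_energy(pwm: EnergyPWM, variant: str) -> float:
    """Predicted additive energy (kT) of a variant; NaN if a coefficient is missing."""
    variant = variant.upper()
    pattern = pwm.library.core_pattern
    if len(variant) != len(pattern) or any(
        b != "N" and variant[i] != b for i, b in enumerate(pattern)
    ):
        raise MembershipError(
            f"{variant!r} does not match library pattern {pattern!r}"
        )
    return float(sum(pwm.beta[(p, variant[p])] for p in pwm.variable_positions))


@dataclass
class LogoMatrix:
    """Mean-centered energy matrix for logo display.

    Each variable column is the four base energies minus their column mean,
    so every column sums to 0; the display matrix is the negation (preferred
    bases up).  Fixed library positions carry no information and are flagged,
    not fitted.
    """

    columns: dict[int, dict[str, float]]  # 0-based position -> base -> centered kT
    fixed_positions: dict[int, str]
    reference_variant: str

    def to_frame(self) -> pd.DataFrame:
        rows = [
            [p + 1] + [self.columns[p][b] for b in BASES]
            for p in sorted(self.columns)
        ]
        return pd.DataFrame(rows, columns=["position", *BASES])

    @property
    def display(self) -> pd.DataFrame:
        """Negated matrix: preferred (low-energy) bases get positive heights."""
        df = self.to_frame()
        df[list(BASES)] = -df[list(BASES)]
        return df


def logo_matrix(pwm: EnergyPWM) -> LogoMatrix:
    """Normalize an ePWM for logo display by mean-centering each column.

    Missing coefficients are centered against the mean of the observed
    entries, so observed entries of every column still sum to 0.
    """
    if not pwm.variable_positions:
        raise ValueError("ePWM has no variable positions")
    cols: dict[int, dict[str, float]] = {}
    for p in pwm.variable_positions:
        vals = np.array([pwm.beta[(p, b)] for b in BASES])
        center = np.nanmean(vals)
        cols[p] = {b: float(vals[i] - center) for i, b in enumerate(BASES)}
    return LogoMatrix(
        columns=cols,
        fixed_positions=pwm.library.fixed_positions,
        reference_variant=pwm.reference_variant,
    )


def render_logo(lm: LogoMatrix, path) -> None:
    """Optional thin rendering layer: stacked-bar energy logo via matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}
    disp = lm.display.set_index("position")
    fig, ax = plt.subplots(figsize=(1.0 + 0.8 * len(disp), 3))
    for pos, row in disp.iterrows():
        up = 0.0
        down = 0.0
        for base in sorted(BASES, key=lambda b: row[b]):
            h = row[base]
            if not math.isfinite(h):
                continue
            if h >= 0:
                ax.bar(pos, h, bottom=up, color=colors[base], width=0.8)
                up += h
            else:
                ax.bar(pos, h, bottom=down, color=colors[base], width=0.8)
                down += h
    for pos, base in sorted(lm.fixed_positions.items()):
        ax.text(pos + 1, 0.02, base, ha="center", color="gray", fontsize=12)
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_xlabel("motif position")
    ax.set_ylabel("-energy (kT)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass
class ComparisonReport:
    """Paired comparison of two energy tables (replicates or genotypes).

    ``noise_level`` splits the paired-difference SD equally between the two
    experiments (sd(a-b)/sqrt(2)), the per-experiment noise under an
    equal-noise assumption; the definition travels in the metadata.
    """

    pearson_r: float
    rms_difference: float
    noise_level: float
    fit_slope: float
    fit_intercept: float
    n_shared: int
    pairs: pd.DataFrame = field(repr=False)
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "rms_difference_kT": self.rms_difference,
            "noise_level_kT": self.noise_level,
            "fit_slope": self.fit_slope,
            "fit_intercept_kT": self.fit_intercept,
            "n_shared": self.n_shared,
            "metadata": self.metadata,
        }


def compare_energy_tables(
    a: EnergyTable, b: EnergyTable, method: str = "ols"
) -> ComparisonReport:
    """Pearson r, RMS difference, per-experiment noise, and best-fit line.

    The line is b regressed on a; ``method="ols"`` is ordinary least squares,
    ``method="tls"`` total least squares (first principal axis).
    """
    ea, eb = a.measured(), b.measured()
    shared = sorted(set(ea) & set(eb))
    if len(shared) < 3:
        raise InsufficientOverlapError(
            f"only {len(shared)} shared variants; need >= 3"
        )
    x = np.array([ea[v] for v in shared])
    y = np.array([eb[v] for v in shared])
    diff = x - y
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        r = float("nan")
    else:
        r = float(stats.pearsonr(x, y).statistic)
    rms = float(np.sqrt(np.mean(diff**2)))
    noise = float(np.std(diff, ddof=1) / math.sqrt(2.0))
    if method == "ols":
        slope, intercept = np.polyfit(x, y, 1)
    elif method == "tls":
        xm, ym = x.mean(), y.mean()
        u, s, vt = np.linalg.svd(np.column_stack([x - xm, y - ym]), full_matrices=False)
        slope = vt[0, 1] / vt[0, 0]
        intercept = ym - slope * xm
    else:
        raise ValueError(f"unknown fit method {method!r}")
    pairs = pd.DataFrame({"variant": shared, "energy_a": x, "energy_b": y})
    return ComparisonReport(
        pearson_r=r,
        rms_difference=rms,
        noise_level=noise,
        fit_slope=float(slope),
        fit_intercept=float(intercept),
        n_shared=len(shared),
        pairs=pairs,
        metadata={
            "noise_definition": "sd(a-b)/sqrt(2), equal-noise split",
            "fit_method": method,
            "units": "kT",
        },
    )
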