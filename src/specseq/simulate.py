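"""Synthetic-data generators.

Two generators live here:

* an equilibrium Spec-seq simulator — a library of sites competes for a
  dilute protein pool; each variant's occupancy follows mass action,
  theta = A e^{-E} / (1 + A e^{-E}), where E is the variant's true additive
  energy (kT) and A is the protein activity ([P] x K_A(ref), unitless).
  Bound/unbound pools are multinomial samples over variants weighted by
  abundance x theta and abundance x (1 - theta); reads are the flanked
  cores with i.i.d. substitution errors.  Because the estimator works on
  odds ratios, A cancels exactly — a property the tests exploit.

* a targetome-table generator — plants dependent-activated / -suppressed /
  independent gene classes into differential ChIP and RNA tables with
  effect sizes truncated strictly inside the classification thresholds,
  puts each gene's peak within 100 kb of its TSS (plus distant decoy
  peaks), and builds a developmental expression matrix in which activated
  genes rise monotonically across five postnatal pseudo-ages.

All randomness flows from one root seed through named child streams, so
every output is bit-reproducible from (config, seed).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .energy_model import EnergyPWM, predict_energy
from .library_design import BASES, SpecseqLibrary
from .read_processing import FractionCounts


def _child_rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic named substream of a root seed (crc32, not Python hash,
    so streams are stable across processes)."""
    key = zlib.crc32(stream.encode()) % 2**31
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# Spec-seq equilibrium simulator
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Ground truth and sampling depths for one simulated Spec-seq experiment.

    activity : unitless protein activity A = [P] x K_A(reference); sets the
        overall bound fraction but cancels from relative energies.
    abundance : per-variant library proportions (default uniform).
    reads_per_fraction : (bound total, unbound total) sequencing depths.
    error_rate : per-base substitution probability applied when reads are
        emitted (not when counts are sampled directly).
    """

    library: SpecseqLibrary
    truth_pwm: EnergyPWM
    activity: float = 1.0
    abundance: dict[str, float] | None = None
    reads_per_fraction: tuple[int, int] = (1_000_000, 1_000_000)
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.activity <= 0:
            raise ValueError("activity must be > 0")
        if not 0.0 <= self.error_rate <= 0.2:
            raise ValueError("error_rate must be in [0, 0.2]")
        if self.abundance is None:
            n = len(self.library.variants)
            self.abundance = {v: 1.0 / n for v in self.library.variants}
        total = sum(self.abundance.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError(f"abundances sum to {total}, not 1")


@dataclass
class TruthBundle:
    """Ground truth echoed alongside simulated counts."""

    energies: dict[str, float]
    theta: dict[str, float]
    expected_bound: dict[str, float]
    expected_unbound: dict[str, float]
    config: SimulationConfig


def occupancy(energy: float, activity: float) -> float:
    """Equilibrium probability that a site of relative energy E (kT) is bound.

    theta = A e^{-E} / (1 + A e^{-E}); strictly decreasing in E and equal to
    A/(1+A) at the reference (E = 0).
    """
    if activity <= 0:
        raise ValueError("activity must be > 0")
    w = activity * math.exp(-energy)
    return w / (1.0 + w)


def simulate_counts(
    cfg: SimulationConfig, mode: str = "sample"
) -> tuple[FractionCounts, TruthBundle]:
    """Simulate bound/unbound per-variant counts under the occupancy model.

    ``mode="sample"`` draws multinomial counts at the configured depths;
    ``mode="expected"`` emits the exact (un-rounded) expected counts, on
    which the energy estimator recovers the truth to machine precision.
    """
    lib = cfg.library
    variants = lib.variants
    energies = {v: predict_energy(cfg.truth_pwm, v) for v in variants}
    if any(not math.isfinite(e) for e in energies.values()):
        raise ValueError("truth ePWM has missing coefficients for some variants")
    theta = {v: occupancy(energies[v], cfg.activity) for v in variants}
    a = np.array([cfg.abundance[v] for v in variants])
    th = np.array([theta[v] for v in variants])
    w_bound = a * th
    w_unbound = a * (1.0 - th)
    for name, w in (("bound", w_bound), ("unbound", w_unbound)):
        if w.sum() <= 0:
            raise ValueError(f"degenerate {name} pool: all occupancies saturate")
    p_bound = w_bound / w_bound.sum()
    p_unbound = w_unbound / w_unbound.sum()
    nb_tot, nu_tot = cfg.reads_per_fraction
    expected_bound = dict(zip(variants, nb_tot * p_bound))
    expected_unbound = dict(zip(variants, nu_tot * p_unbound))
    if mode == "expected":
        counts = {
            v: (expected_bound[v], expected_unbound[v]) for v in variants
        }
    elif mode == "sample":
        rng = _child_rng(cfg.seed, "counts")
        nb = rng.multinomial(nb_tot, p_bound)
        nu = rng.multinomial(nu_tot, p_unbound)
        counts = {v: (float(b), float(u)) for v, b, u in zip(variants, nb, nu)}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    fc = FractionCounts(library=lib, counts=counts)
    truth = TruthBundle(
        energies=energies,
        theta=theta,
        expected_bound=expected_bound,
        expected_unbound=expected_unbound,
        config=cfg,
    )
    return fc, truth


def _mutate_block(seqs: np.ndarray, error_rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Apply i.i.d. substitutions to an (n, L) array of base indices 0..3."""
    mask = rng.random(seqs.shape) < error_rate
    if mask.any():
        # shift by 1..3 mod 4: guaranteed a *different* base
        shifts = rng.integers(1, 4, size=int(mask.sum()))
        seqs = seqs.copy()
        seqs[mask] = (seqs[mask] + shifts) % 4
    return seqs


def emit_reads(
    fc: FractionCounts,
    library: SpecseqLibrary | None = None,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Expand counts into (name, sequence) reads per fraction.

    Each counted molecule becomes flank5+core+flank3 with i.i.d. per-base
    substitutions at ``error_rate``; names encode fraction and serial.
    Float counts (expected mode) are rounded to integers.
    """
    library = library or fc.library
    base_idx = {b: i for i, b in enumerate(BASES)}
    idx_base = np.array(list(BASES))
    out: list[list[tuple[str, str]]] = []
    for fraction, col in (("bound", 0), ("unbound", 1)):
        rng = _child_rng(seed, f"reads-{fraction}")
        reads: list[tuple[str, str]] = []
        serial = 0
        for v in library.variants:
            n = int(round(fc.counts[v][col]))
            if n <= 0:
                continue
            full = library.full_sequence(v)
            if error_rate == 0.0:
                for _ in range(n):
                    reads.append((f"{fraction}:{serial}", full))
                    serial += 1
            else:
                arr = np.array([base_idx[b] for b in full], dtype=np.int8)
                block = np.broadcast_to(arr, (n, arr.size))
                block = _mutate_block(block, error_rate, rng)
                for row in block:
                    reads.append((f"{fraction}:{serial}", "".join(idx_base[row])))
                    serial += 1
        out.append(reads)
    return out[0], out[1]


def make_truth_pwm(
    library: SpecseqLibrary,
    reference_variant: str,
    energy_scale: float = 1.0,
    seed: int = 0,
) -> EnergyPWM:
    """Random ground-truth additive energy model for a library.

    Non-reference bases get i.i.d. Uniform(0, energy_scale) kT penalties, so
    the worst variant sits at ~(number of variable positions) x scale.
    """
    from .energy_model import FitStats  # local import to avoid cycle at module load

    rng = _child_rng(seed, "truth-pwm")
    varpos = library.variable_positions
    beta: dict[tuple[int, str], float] = {}
    for p in varpos:
        ref_base = reference_variant[p]
        for b in BASES:
            beta[(p, b)] = 0.0 if b == ref_base else float(
                rng.uniform(0.0, energy_scale)
            )
    return EnergyPWM(
        library=library,
        reference_variant=reference_variant,
        beta=beta,
        fit=FitStats(r_squared=1.0, residual_sd=0.0, n_variants_fit=0),
    )


# ---------------------------------------------------------------------------
# Targetome table simulator
# ---------------------------------------------------------------------------

#: classification class labels, shared with specseq.targetome
CLASSES = ("dependent_activated", "dependent_suppressed", "independent")

PSEUDO_AGES = ("P3", "P7", "P10", "P14", "P21")

_GENE_SPACING = 1_000_000  # bp between synthetic TSSs; >> the 100 kb window


@dataclass
class TargetomeTables:
    """Synthetic inputs for the targetome classification stage plus truth."""

    chip: pd.DataFrame          # peak id -> log2FC, fdr, cpm
    rna_p10: pd.DataFrame       # gene id -> log2FC, fdr, cpm
    rna_p21: pd.DataFrame
    peaks: pd.DataFrame         # BED-like: chrom, start, end, name
    tss: pd.DataFrame           # BED-like points: chrom, start, end, name
    dev_expr: pd.DataFrame      # genes x pseudo-ages, cpm
    truth_labels: pd.Series     # gene id -> class (incl. "unassigned")
    truth_lost_peaks: frozenset[str]


def _trunc_normal(rng, mean, sd, upper=None, lower=None):
    a = -np.inf if lower is None else (lower - mean) / sd
    b = np.inf if upper is None else (upper - mean) / sd
    return float(
        stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)
    )


def simulate_targetome_tables(
    n_genes: int = 400,
    class_proportions: dict[str, float] | None = None,
    n_no_peak_genes: int = 40,
    n_decoy_peaks: int = 30,
    effect_mean: float = -2.0,
    effect_sd: float = 0.5,
    seed: int = 0,
) -> TargetomeTables:
    """Plant gene classes into differential tables, peaks/TSSs, and a
    developmental expression matrix.

    Every classed gene gets one *lost* peak strictly within 100 kb of its
    TSS (ChIP log2FC truncated < -1.1, FDR << 5e-2); dependent genes add a
    P21 expression change truncated strictly past the +-0.6 / 1e-5 class
    thresholds while independent genes stay null.  ``n_no_peak_genes`` extra
    genes carry no lost peak (truth label "unassigned"): half have no peak
    at all, half a *retained* peak (null ChIP change) to exercise the
    lost-peak filter.  Decoy lost peaks sit > 100 kb from every TSS.
    Activated genes rise monotonically across the five pseudo-ages of the
    developmental matrix.
    """
    if class_proportions is None:
        class_proportions = {
            "dependent_activated": 0.30,
            "dependent_suppressed": 0.10,
            "independent": 0.60,
        }
    if not math.isclose(sum(class_proportions.values()), 1.0, rel_tol=1e-9):
        raise ValueError("class proportions must sum to 1")
    rng = _child_rng(seed, "targetome")

    n_act = int(round(n_genes * class_proportions["dependent_activated"]))
    n_sup = int(round(n_genes * class_proportions["dependent_suppressed"]))
    n_ind = n_genes - n_act - n_sup
    labels = (
        ["dependent_activated"] * n_act
        + ["dependent_suppressed"] * n_sup
        + ["independent"] * n_ind
    )
    genes = [f"gene{i:05d}" for i in range(n_genes + n_no_peak_genes)]
    labels += ["unassigned"] * n_no_peak_genes
    truth = pd.Series(labels, index=genes, name="class")

    # --- coordinates: one synthetic chromosome, TSSs 1 Mb apart ----------
    tss_pos = np.arange(len(genes)) * _GENE_SPACING + 500_000
    tss = pd.DataFrame(
        {"chrom": "chrS", "start": tss_pos, "end": tss_pos + 1, "name": genes}
    )
    peak_rows = []
    chip_rows = []
    for i, g in enumerate(genes):
        cls = truth[g]
        if cls == "unassigned" and i % 2 == 0:
            continue  # half the unassigned genes have no peak at all
        dist = int(rng.integers(1_000, 90_000))
        sign = 1 if rng.random() < 0.5 else -1
        mid = tss_pos[i] + sign * dist
        pid = f"peak_{g}"
        peak_rows.append(("chrS", mid - 100, mid + 100, pid))
        if cls == "unassigned":  # retained peak: survives the loss filter
            lfc = float(np.clip(rng.normal(0.0, 0.2), -0.5, 0.5))
            fdr = float(rng.uniform(0.2, 0.9))
        else:  # every classed gene's peak is lost in the mutant
            lfc = _trunc_normal(rng, effect_mean, effect_sd, upper=-1.1)
            fdr = float(rng.uniform(1e-6, 1e-3))
        chip_rows.append((pid, lfc, fdr, float(rng.uniform(5, 100))))
    # decoy lost peaks, > 100 kb from every TSS (150-350 kb past a TSS)
    for d in range(n_decoy_peaks):
        anchor = int(rng.integers(0, len(genes)))
        mid = tss_pos[anchor] + int(rng.integers(150_000, 350_000))
        pid = f"peak_decoy{d:03d}"
        peak_rows.append(("chrS", mid - 100, mid + 100, pid))
        lfc = _trunc_normal(rng, effect_mean, effect_sd, upper=-1.1)
        chip_rows.append((pid, lfc, float(rng.uniform(1e-6, 1e-3)),
                          float(rng.uniform(5, 100))))
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "name"])
    chip = pd.DataFrame(chip_rows, columns=["id", "log2FC", "fdr", "cpm"]).set_index("id")

    truth_lost = frozenset(
        [f"peak_{g}" for g in genes[:n_genes]]
        + [f"peak_decoy{d:03d}" for d in range(n_decoy_peaks)]
    )

    # --- RNA differential tables ----------------------------------------
    def rna_table(attenuation: float, fdr_hi: float) -> pd.DataFrame:
        rows = []
        for g in genes:
            cls = truth[g]
            cpm = float(rng.uniform(5, 500))
            if cls == "dependent_activated":
                lfc = float(
                    _trunc_normal(rng, effect_mean * attenuation, effect_sd,
                                  upper=-0.7)
                )
                fdr = float(rng.uniform(1e-12, 1e-6))
            elif cls == "dependent_suppressed":
                lfc = float(
                    _trunc_normal(rng, -effect_mean * attenuation, effect_sd,
                                  lower=0.7)
                )
                fdr = float(rng.uniform(1e-12, 1e-6))
            else:  # independent and unassigned genes: null expression change
                lfc = float(np.clip(rng.normal(0.0, 0.2), -0.5, 0.5))
                fdr = float(rng.uniform(0.1, fdr_hi))
            rows.append((g, lfc, fdr, cpm))
        return pd.DataFrame(rows, columns=["id", "log2FC", "fdr", "cpm"]).set_index("id")

    rna_p21 = rna_table(attenuation=1.0, fdr_hi=0.9)
    rna_p10 = rna_table(attenuation=0.5, fdr_hi=0.9)

    # --- developmental expression matrix --------------------------------
    n_ages = len(PSEUDO_AGES)
    base = rng.lognormal(mean=3.0, sigma=0.8, size=len(genes))
    growth = rng.uniform(1.6, 3.0, size=len(genes))
    expr = np.empty((len(genes), n_ages))
    for j in range(n_ages):
        noise = rng.lognormal(mean=0.0, sigma=0.05, size=len(genes))
        flat = base * noise
        rising = base * growth ** j * noise
        is_act = (truth.values == "dependent_activated")
        expr[:, j] = np.where(is_act, rising, flat)
    dev_expr = pd.DataFrame(expr, index=genes, columns=list(PSEUDO_AGES))

    return TargetomeTables(
        chip=chip,
        rna_p10=rna_p10,
        rna_p21=rna_p21,
        peaks=peaks,
        tss=tss,
        dev_expr=dev_expr,
        truth_labels=truth,
        truth_lost_peaks=truth_lost,
    )
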