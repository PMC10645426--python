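"""Threshold-based TF-dependence classification and developmental correlation.

Works on generic differential tables (id -> log2FC, FDR, cpm): peaks lost in
a loss-of-function mutant (log2FC < -1, FDR < 5e-2) are assigned to the
closest TSS within 100 kb; peak-associated genes are then classed by the
mutant's adult expression change (activated if log2FC < -0.6 and FDR < 1e-5,
suppressed if log2FC > 0.6 and FDR < 1e-5, otherwise independent).  All
thresholds are strict inequalities.  A sample-wise Pearson correlation of a
gene set's expression against a developmental reference places each sample
on a maturation axis.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DIFFERENTIAL_COLUMNS = ("log2FC", "fdr", "cpm")

CLASS_LABELS = (
    "dependent_activated",
    "dependent_suppressed",
    "independent",
    "unassigned",
    "missing_expression",
)


def validate_differential(df: pd.DataFrame, name: str = "table") -> pd.DataFrame:
    """Check a differential table: unique ids, required columns, FDR in [0,1]."""
    missing = set(DIFFERENTIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{name} lacks columns {sorted(missing)}")
    if not df.index.is_unique:
        raise ValueError(f"{name} has duplicate ids")
    if ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
        raise ValueError(f"{name} has FDR outside [0, 1]")
    return df


def lost_peaks(
    chip: pd.DataFrame, fc_cut: float = -1.0, fdr_cut: float = 5e-2
) -> set[str]:
    """Peaks bound in WT but lost in the mutant: log2FC < fc_cut AND FDR < fdr_cut.

    Both inequalities are strict; a peak at exactly the cut is retained.
    """
    validate_differential(chip, "chip")
    sel = (chip["log2FC"] < fc_cut) & (chip["fdr"] < fdr_cut)
    return set(chip.index[sel])


@dataclass
class PeakGeneMap:
    """Peak -> (closest gene, distance) assignments within a distance cap."""

    assignments: dict[str, tuple[str, float]]
    unassigned: frozenset[str]
    max_distance: float
    provenance: dict = field(default_factory=dict)

    def genes_for(self, peak_ids: set[str]) -> set[str]:
        """Genes with at least one assigned peak among ``peak_ids``."""
        return {
            self.assignments[p][0] for p in peak_ids if p in self.assignments
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (p, g, d) for p, (g, d) in sorted(self.assignments.items())
        ] + [(p, "", np.nan) for p in sorted(self.unassigned)]
        return pd.DataFrame(rows, columns=["peak", "gene", "distance"])


def assign_peaks(
    peaks: pd.DataFrame, tss: pd.DataFrame, max_distance: float = 100_000
) -> PeakGeneMap:
    """Assign each peak to the closest TSS within ``max_distance`` bp.

    Peak position is the interval midpoint; TSS is a single base (BED start).
    Comparison is per chromosome; exact distance ties break to the
    lexicographically smallest gene id.  Peaks farther than the cap from
    every TSS are unassigned.
    """
    for df, label in ((peaks, "peaks"), (tss, "tss")):
        need = {"chrom", "start", "end", "name"}
        if not need.issubset(df.columns):
            raise ValueError(f"{label} table lacks columns {sorted(need - set(df.columns))}")
    assignments: dict[str, tuple[str, float]] = {}
    unassigned: set[str] = set()
    tss_by_chrom = {
        chrom: grp.sort_values(["start", "name"]).reset_index(drop=True)
        for chrom, grp in tss.groupby("chrom")
    }
    for _, peak in peaks.iterrows():
        mid = (peak["start"] + peak["end"]) / 2.0
        grp = tss_by_chrom.get(peak["chrom"])
        if grp is None:
            unassigned.add(peak["name"])
            continue
        dist = np.abs(grp["start"].to_numpy(dtype=float) - mid)
        best = dist.min()
        if best > max_distance:
            unassigned.add(peak["name"])
            continue
        candidates = sorted(grp["name"][dist == best])
        assignments[peak["name"]] = (candidates[0], float(best))
    return PeakGeneMap(
        assignments=assignments,
        unassigned=frozenset(unassigned),
        max_distance=max_distance,
        provenance={"position": "peak midpoint vs TSS base",
                    "tie_break": "lexicographically smallest gene id"},
    )


@dataclass
class GeneClassTable:
    """Gene -> dependence class labels, plus the thresholds that made them."""

    labels: dict[str, str]
    provenance: dict = field(default_factory=dict)

    def counts(self) -> Counter:
        return Counter(self.labels.values())

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.labels.items())
        return pd.DataFrame(rows, columns=["gene", "class"])


def classify_genes(
    lost: set[str],
    peak_map: PeakGeneMap,
    rna_p21: pd.DataFrame,
    act_fc: float = -0.6,
    sup_fc: float = 0.6,
    fdr_cut: float = 1e-5,
) -> GeneClassTable:
    """Class every gene by lost-peak association and adult expression change.

    Universe = genes in the RNA table plus genes carrying an assigned lost
    peak.  A gene with no assigned lost peak is ``unassigned``; with a lost
    peak but no expression record, ``missing_expression``; otherwise
    activated / suppressed / independent by strict thresholds on the adult
    mutant log2FC and FDR ("not significantly affected" is the complement:
    FDR >= fdr_cut or |log2FC| <= the class cut).
    """
    validate_differential(rna_p21, "rna_p21")
    lost_genes = peak_map.genes_for(lost)
    universe = set(rna_p21.index) | lost_genes
    labels: dict[str, str] = {}
    for g in universe:
        if g not in lost_genes:
            labels[g] = "unassigned"
        elif g not in rna_p21.index:
            labels[g] = "missing_expression"
        else:
            lfc = rna_p21.at[g, "log2FC"]
            fdr = rna_p21.at[g, "fdr"]
            if lfc < act_fc and fdr < fdr_cut:
                labels[g] = "dependent_activated"
            elif lfc > sup_fc and fdr < fdr_cut:
                labels[g] = "dependent_suppressed"
            else:
                labels[g] = "independent"
    return GeneClassTable(
        labels=labels,
        provenance={
            "act_fc": act_fc,
            "sup_fc": sup_fc,
            "fdr_cut": fdr_cut,
            "universe": "rna table genes + lost-peak-associated genes",
            "independent_rule": f"fdr >= {fdr_cut} or |log2FC| <= {sup_fc}",
        },
    )


def call_deg(
    diff: pd.DataFrame,
    fc_abs: float = 1.0,
    fdr_cut: float = 1e-2,
    cpm_min: float = 5.0,
) -> pd.DataFrame:
    """Differentially expressed genes: cpm >= cpm_min, |log2FC| > fc_abs, FDR < fdr_cut.

    The cpm floor is inclusive; the fold-change and FDR cuts are strict.
    Returns a frame of the called genes with an up/down direction tag.
    """
    validate_differential(diff, "diff")
    sel = (
        (diff["cpm"] >= cpm_min)
        & (diff["log2FC"].abs() > fc_abs)
        & (diff["fdr"] < fdr_cut)
    )
    called = diff.loc[sel].copy()
    called["direction"] = np.where(called["log2FC"] > 0, "up", "down")
    return called[["log2FC", "fdr", "cpm", "direction"]].sort_index()


def developmental_correlation(
    query: pd.DataFrame,
    reference: pd.DataFrame,
    gene_set: set[str] | list[str],
    transform: str = "log2cpm1",
) -> pd.DataFrame:
    """Sample-wise Pearson correlation of a gene set between two matrices.

    Both matrices are genes x samples (cpm).  Shared genes restricted to
    ``gene_set`` (>= 3 required) are transformed (default log2(cpm+1);
    also ``"raw"`` or per-gene ``"zscore"``) and each query sample is
    correlated against each reference sample.
    """
    shared = sorted(set(gene_set) & set(query.index) & set(reference.index))
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} genes shared between gene set and matrices; need >= 3"
        )
    q = query.loc[shared].to_numpy(dtype=float)
    r = reference.loc[shared].to_numpy(dtype=float)
    if transform == "log2cpm1":
        q, r = np.log2(q + 1.0), np.log2(r + 1.0)
    elif transform == "zscore":
        def z(m):
            mu = m.mean(axis=1, keepdims=True)
            sd = m.std(axis=1, keepdims=True)
            sd[sd == 0] = 1.0
            return (m - mu) / sd
        q, r = z(q), z(r)
    elif transform != "raw":
        raise ValueError(f"unknown transform {transform!r}")
    out = np.empty((q.shape[1], r.shape[1]))
    for i in range(q.shape[1]):
        for j in range(r.shape[1]):
            out[i, j] = np.corrcoef(q[:, i], r[:, j])[0, 1]
    return pd.DataFrame(out, index=query.columns, columns=reference.columns)
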