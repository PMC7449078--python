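"""Comparing recentered parameter sets between environments and genomes.

Comparisons operate on the recentered per-codon values (deviations from each
family's mean), one value per codon, so the choice of reference codon cannot
affect them. Association is summarized by the Pearson correlation plus a
type II (major-axis) regression, appropriate because both parameter sets
carry estimation error. Candidate donor lineages for an introgression are
ranked by the correlation of their mutation bias ΔM with the exogenous gene
set's ΔM — mutation bias decays slowest and discriminates lineages best.
Lineages using the alternative yeast nuclear code have their leucine family
excluded from the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .params import MutSelParams


def _comparable_values(
    params_a: MutSelParams,
    params_b: MutSelParams,
    kind: str,
    excluded_families: set[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    excluded = set(excluded_families or ())
    for p in (params_a, params_b):
        excluded |= {f.label for f in p.table.families if f.excluded_from_comparison}
    table = params_a.table
    xs, ys = [], []
    for fam in table.families:
        if fam.label in excluded:
            continue
        try:
            y = params_b.family_values(fam.label, kind)
        except KeyError:
            continue
        x = params_a.family_values(fam.label, kind)
        if len(x) != len(y):
            continue  # family differs between codes (e.g. Leu under table 12)
        xs.append(x)
        ys.append(y)
    return np.concatenate(xs), np.concatenate(ys)


def correlate(
    params_a: MutSelParams,
    params_b: MutSelParams,
    kind: str = "delta_m",
    excluded_families: set[str] | None = None,
) -> tuple[float, float]:
    """Pearson correlation of recentered per-codon values; returns (ρ, p)."""
    x, y = _comparable_values(params_a, params_b, kind, excluded_families)
    if len(x) < 3:
        raise ValueError("fewer than 3 shared values to correlate")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def type2_regression(x, y) -> tuple[float, float]:
    """Major-axis (type II) regression slope and intercept.

    The slope comes from the principal eigenvector of the 2×2 covariance
    matrix; the line passes through the centroid. Symmetric in x and y in
    the sense that slope(x, y) = 1/slope(y, x).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need at least 3 paired points")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in x or y")
    cov = np.cov(x, y)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]
    if v[0] == 0:
        raise ValueError("major axis is vertical; slope undefined")
    slope = v[1] / v[0]
    intercept = y.mean() - slope * x.mean()
    return float(slope), float(intercept)


def sign_agreement(
    params_a: MutSelParams,
    params_b: MutSelParams,
    kind: str = "delta_m",
    excluded_families: set[str] | None = None,
) -> pd.DataFrame:
    """Per-codon flag for whether the two parameter sets share the sign."""
    excluded = set(excluded_families or ())
    rows = []
    for fam in params_a.table.families:
        if fam.label in excluded:
            continue
        a = params_a.family_values(fam.label, kind)
        b = params_b.family_values(fam.label, kind)
        for codon, va, vb in zip(fam.codons, a, b):
            rows.append(
                {
                    "family": fam.label,
                    "codon": codon,
                    "a": va,
                    "b": vb,
                    "same_sign": bool(np.sign(va) == np.sign(vb)),
                }
            )
    return pd.DataFrame(rows)


def optimal_codons(params: MutSelParams, tol: float = 0.0) -> pd.DataFrame:
    """Mutationally and selectively favored codon per family.

    The mutationally favored codon minimizes ΔM (highest equilibrium
    frequency at φ = 0); the selectively favored codon minimizes Δη (its
    usage increases with φ). Exact ties report all tied codons, flagged.
    """
    params = params.recenter()
    rows = []
    for fam in params.table.families:
        entry: dict = {"family": fam.label}
        for kind, col in (("delta_m", "mutationally_favored"), ("delta_eta", "selectively_favored")):
            vals = params.family_values(fam.label, kind)
            best = vals.min()
            winners = [c for c, v in zip(fam.codons, vals) if v <= best + tol]
            entry[col] = ",".join(winners)
            entry[col + "_tie"] = len(winners) > 1
        rows.append(entry)
    return pd.DataFrame(rows)


@dataclass
class LineageRanking:
    """Candidate donor lineages ordered by similarity in mutation bias."""

    frame: pd.DataFrame  # lineage, rho_dm, p_dm, rho_de, p_de, top10, annotations

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.frame.head(n)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def rank_candidate_lineages(
    exogenous: MutSelParams,
    lineages: dict[str, MutSelParams],
    annotations: pd.DataFrame | None = None,
    top_n: int = 10,
) -> LineageRanking:
    """Rank lineages by Pearson ρ of ΔM against the exogenous parameters.

    ``annotations`` (optional, indexed by lineage id) may carry externally
    computed columns such as GC content, synteny %, or divergence time; they
    are joined onto the ranking untouched.
    """
    rows = []
    for lineage_id, params in lineages.items():
        rho_dm, p_dm = correlate(exogenous, params, "delta_m")
        rho_de, p_de = correlate(exogenous, params, "delta_eta")
        rows.append(
            {
                "lineage": lineage_id,
                "rho_delta_m": rho_dm,
                "p_delta_m": p_dm,
                "rho_delta_eta": rho_de,
                "p_delta_eta": p_de,
                "alternative_code": any(
                    f.excluded_from_comparison for f in params.table.families
                ),
            }
        )
    frame = pd.DataFrame(rows).sort_values(
        ["rho_delta_m", "lineage"], ascending=[False, True], kind="mergesort"
    )
    frame["rank"] = np.arange(1, len(frame) + 1)
    frame["top_candidate"] = frame["rank"] <= top_n
    if annotations is not None:
        frame = frame.join(annotations, on="lineage")
    return LineageRanking(frame.reset_index(drop=True))


def comparison_report(
    params_a: MutSelParams,
    params_b: MutSelParams,
    excluded_families: set[str] | None = None,
) -> pd.DataFrame:
    """Correlation, MA regression, and sign agreement for ΔM and Δη."""
    rows = []
    for kind in ("delta_m", "delta_eta"):
        x, y = _comparable_values(params_a, params_b, kind, excluded_families)
        rho, p = stats.pearsonr(x, y)
        slope, intercept = type2_regression(x, y)
        agree = float(np.mean(np.sign(x) == np.sign(y)))
        rows.append(
            {
                "kind": kind,
                "pearson_rho": float(rho),
                "p_value": float(p),
                "ma_slope": slope,
                "ma_intercept": intercept,
                "sign_agreement": agree,
                "n_codons": len(x),
            }
        )
    return pd.DataFrame(rows)
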