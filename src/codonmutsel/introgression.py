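"""Dating an introgression with a two-allele codon-frequency decay clock.

For a two-codon synonymous family, mutation alone drives the frequency c₁ of
the (alphabetically) first codon toward the host's mutation equilibrium

    dc₁/dt = −μ₁₂·c₁ + μ₂₁·(1 − c₁),       c₁* = μ₂₁/(μ₁₂ + μ₂₁)

Writing the host's pairwise mutation contrast ΔM_endo = ΔM₁ − ΔM₂, the
equilibrium is c₁* = 1/(1 + exp[ΔM_endo]) and the off-rate follows as
μ₁₂ = μ₂₁·exp[ΔM_endo]. The solution is a single exponential relaxation

    c₁(t) = c₁* + (c₁(0) − c₁*)·exp[−(μ₁₂ + μ₂₁)·t]

Given mutation contrasts for the *source* lineage (frequencies at the time
of introgression), the *exogenous* gene set (frequencies now) and the
*endogenous* host genome (the equilibrium being approached), the elapsed
time solves in closed form per family; the genome-wide age is the mean over
eligible two-codon families with its standard error. The same clock run
forward gives the horizon at which the exogenous signal will have decayed to
within a tolerance of the host equilibrium. Families whose current frequency
is not between the initial frequency and the equilibrium cannot be reached
by monotone decay and are excluded with a reason.

Ages are in generations of the default mutation rate's units
(μ₂₁ = 3.8×10⁻¹⁰ per nucleotide per generation); use
:func:`generations_to_years` for calendar conversions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import MutSelParams

MU_21_DEFAULT = 3.8e-10

_EPS = 1e-12


def pairwise_contrast(recentered_dm: np.ndarray) -> float:
    """ΔM₁ − ΔM₂ of a two-codon family (= 2·ΔM₁ in recentered form).

    The implied mutation equilibrium of codon 1 is 1/(1 + exp[contrast]).
    """
    recentered_dm = np.asarray(recentered_dm, dtype=float)
    if recentered_dm.shape != (2,):
        raise ValueError("pairwise contrast requires a family of exactly 2 codons")
    return float(recentered_dm[0] - recentered_dm[1])


def equilibrium_frequency(contrast: float) -> float:
    """Mutation-equilibrium frequency of codon 1, c₁* = 1/(1 + exp[contrast])."""
    return float(1.0 / (1.0 + np.exp(contrast)))


def decay_trajectory(
    c0: float, contrast: float, mu_21: float = MU_21_DEFAULT, t: float = 0.0
) -> float:
    """Codon-1 frequency after t generations of mutational decay from c0."""
    if not 0 < c0 < 1:
        raise ValueError("c0 must lie in (0, 1)")
    if t < 0:
        raise ValueError("t must be >= 0")
    c_star = equilibrium_frequency(contrast)
    rate = mu_21 * (1.0 + np.exp(contrast))  # μ₁₂ + μ₂₁
    return float(c_star + (c0 - c_star) * np.exp(-rate * t))


def time_to_frequency(
    c0: float, c_target: float, contrast: float, mu_21: float = MU_21_DEFAULT
) -> float:
    """Generations for the frequency to decay from c0 to c_target.

    Defined only when c_target lies between c0 and the equilibrium (monotone
    decay); otherwise raises ValueError.
    """
    if not (0 < c0 < 1 and 0 < c_target < 1):
        raise ValueError("frequencies must lie in (0, 1)")
    c_star = equilibrium_frequency(contrast)
    num = c_target - c_star
    den = c0 - c_star
    if abs(c_target - c0) < _EPS * max(1.0, abs(c0)):
        return 0.0
    if abs(den) < _EPS:
        raise ValueError("initial frequency is at equilibrium; no decay occurs")
    ratio = num / den
    if ratio <= 0 or ratio > 1 + _EPS:
        raise ValueError("unreachable under monotone decay")
    rate = mu_21 * (1.0 + np.exp(contrast))
    return float(-np.log(min(ratio, 1.0)) / rate)


@dataclass
class DecayClockResult:
    """Per-family ages/horizons with genome aggregates."""

    per_family: pd.DataFrame  # family, c0, c_now, c_star, generations, included, reason
    mu_21: float
    mean_generations: float = field(init=False)
    se_generations: float = field(init=False)

    def __post_init__(self):
        vals = self.per_family.loc[self.per_family["included"], "generations"]
        self.mean_generations = float(vals.mean()) if len(vals) else np.nan
        self.se_generations = (
            float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
        )

    @property
    def included_families(self) -> list[str]:
        return list(self.per_family.loc[self.per_family["included"], "family"])

    @property
    def excluded_families(self) -> dict[str, str]:
        bad = self.per_family.loc[~self.per_family["included"]]
        return dict(zip(bad["family"], bad["reason"]))

    def years(self, generations_per_day: float) -> tuple[float, float]:
        """(mean, SE) converted to years at a given generations/day."""
        return (
            generations_to_years(self.mean_generations, generations_per_day),
            generations_to_years(self.se_generations, generations_per_day),
        )

    def to_tsv(self, path) -> None:
        self.per_family.to_csv(path, sep="\t", index=False)


def _two_codon_contrasts(
    params: MutSelParams, include_z: bool = True
) -> dict[str, float]:
    params = params.recenter()
    return {
        fam.label: pairwise_contrast(params.family_values(fam.label, "delta_m"))
        for fam in params.table.two_codon_families(include_z)
    }


def introgression_age(
    source: MutSelParams,
    exogenous: MutSelParams,
    endogenous: MutSelParams,
    mu_21: float = MU_21_DEFAULT,
    include_z: bool = True,
) -> DecayClockResult:
    """Elapsed generations since introgression, per two-codon family.

    Initial frequencies come from the source lineage's mutation contrasts,
    current frequencies from the exogenous gene set's, and the equilibrium
    from the host's endogenous contrasts.
    """
    cs = _two_codon_contrasts(source, include_z)
    cx = _two_codon_contrasts(exogenous, include_z)
    ce = _two_codon_contrasts(endogenous, include_z)
    rows = []
    for fam in sorted(cs):
        c0 = equilibrium_frequency(cs[fam])
        c_now = equilibrium_frequency(cx[fam])
        c_star = equilibrium_frequency(ce[fam])
        row = {"family": fam, "c0": c0, "c_now": c_now, "c_star": c_star}
        try:
            t = time_to_frequency(c0, c_now, ce[fam], mu_21)
            row.update(generations=t, included=True, reason="")
        except ValueError as err:
            row.update(generations=np.nan, included=False, reason=str(err))
        rows.append(row)
    result = DecayClockResult(pd.DataFrame(rows), mu_21)
    if not result.included_families:
        raise ValueError("all two-codon families excluded; no age estimate possible")
    return result


def decay_horizon(
    exogenous: MutSelParams,
    endogenous: MutSelParams,
    mu_21: float = MU_21_DEFAULT,
    tolerance: float = 0.01,
    relative: bool = True,
    include_z: bool = True,
) -> DecayClockResult:
    """Generations until the exogenous signal sits within tolerance of the host.

    With ``relative=True`` (default) the target band is |c − c*| ≤ tol·c*;
    otherwise an absolute band |c − c*| ≤ tol.
    """
    if not 0 < tolerance < 1:
        raise ValueError("tolerance must lie in (0, 1)")
    cx = _two_codon_contrasts(exogenous, include_z)
    ce = _two_codon_contrasts(endogenous, include_z)
    rows = []
    for fam in sorted(cx):
        c_now = equilibrium_frequency(cx[fam])
        c_star = equilibrium_frequency(ce[fam])
        band = tolerance * c_star if relative else tolerance
        row = {"family": fam, "c0": c_now, "c_now": np.nan, "c_star": c_star}
        if abs(c_now - c_star) <= band:
            row.update(generations=0.0, included=True, reason="already within tolerance")
        else:
            target = c_star + np.sign(c_now - c_star) * band
            try:
                t = time_to_frequency(c_now, target, ce[fam], mu_21)
                row.update(generations=t, included=True, reason="")
            except ValueError as err:
                row.update(generations=np.nan, included=False, reason=str(err))
        rows.append(row)
    return DecayClockResult(pd.DataFrame(rows), mu_21)


def generations_to_years(generations: float, generations_per_day: float) -> float:
    """Calendar years for a generation count at a given generations/day."""
    if generations_per_day <= 0:
        raise ValueError("generations_per_day must be positive")
    if generations < 0:
        raise ValueError("generations must be non-negative")
    return float(generations / (generations_per_day * 365.0))
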