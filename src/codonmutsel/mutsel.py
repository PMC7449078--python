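"""Mutation-selection model of synonymous codon usage and its Bayesian fit.

The model: within each synonymous family the probability of observing codon
``i`` in a gene with protein synthesis rate φ is

    p_i ∝ exp(−ΔM_i − Δη_i · φ)

where ΔM is the mutation bias (governs usage at φ = 0) and Δη the selection
bias relative to drift for a gene of average expression. Protein synthesis
rates are unitless with mean 1 over the fitted gene set. Gene likelihoods
are products of per-codon categorical probabilities given the gene's
amino-acid usage (the multinomial coefficient, constant in the parameters,
is omitted throughout).

Inference is Metropolis-within-Gibbs: per-family joint random-walk updates
of the raw (ΔM, Δη) vectors (one reference codon per family pinned at 0 for
identifiability; recentering to family-mean deviations is applied only at
reporting), vectorized per-gene log-scale random-walk updates of φ, and a
random-walk update of the lognormal prior scale σ_φ. Proposal scales adapt
toward a 0.2–0.4 acceptance rate during burn-in and are frozen afterward.
The posterior has a near-exact mirror mode (ΔM → ΔM + 2Δη, Δη → −Δη,
φ → 2 − φ, broken only by genes with φ > 2), so the fit launches several
short pilot chains from dispersed starting values and continues the one
with the highest log posterior — mirroring the multiple-starting-value
practice of this model's reference workflow.

The public surface is the scikit-learn style estimator
:class:`CodonUsageModel` plus thin functional wrappers
(:func:`codon_probabilities`, :func:`gene_loglik`, :func:`fit`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .codon_data import ENDOGENOUS, EXOGENOUS, GeneCodonCounts, GenomeCounts, GenomePartition
from .families import CodonFamilyTable
from .params import MutSelParams

COMBINED = "combined"
SEPARATED = "separated"

_ACCEPT_TARGET = 0.3


# ---------------------------------------------------------------------------
# stationary model


def codon_probabilities(params: MutSelParams, family: str, phi: float) -> np.ndarray:
    """Stationary codon probabilities of one family at synthesis rate φ.

    Computed as a max-subtracted softmax of −(ΔM + Δη·φ), so it is invariant
    under recentering and safe against overflow. At φ = 0 this reduces to the
    mutation equilibrium exp(−ΔM_i)/Σ_j exp(−ΔM_j).
    """
    if not np.isfinite(phi) or phi < 0:
        raise ValueError(f"phi must be finite and >= 0, got {phi}")
    idx = params.table.slice(family)
    logits = -(params.delta_m[idx] + params.delta_eta[idx] * phi)
    logits -= logits.max()
    p = np.exp(logits)
    return p / p.sum()


def recenter(params: MutSelParams) -> MutSelParams:
    """Express ΔM and Δη as deviations from each family's mean."""
    return params.recenter()


def gene_loglik(counts: GeneCodonCounts, params: MutSelParams, phi: float) -> float:
    """Log-likelihood Σ_i n_i·log p_i of one gene (multinomial coefficient omitted)."""
    total = 0.0
    for fam in params.table.families:
        idx = params.table.slice(fam.label)
        n = counts.counts[idx]
        if n.sum() == 0:
            continue
        logits = -(params.delta_m[idx] + params.delta_eta[idx] * phi)
        logp = logits - logsumexp(logits)
        total += float(n @ logp)
    return total


# ---------------------------------------------------------------------------
# posterior trace


@dataclass
class PosteriorTrace:
    """Thinned MCMC samples plus enough structure to rebuild parameter sets.

    ``samples`` columns follow the layout: for each environment the free raw
    ΔM entries (one per non-reference codon), then the free raw Δη entries,
    then log φ per gene, then log σ_φ. ``log_post`` is the unnormalized log
    posterior density *in the sampled coordinates* (log φ, log σ_φ), which is
    what the marginal-likelihood estimator needs.
    """

    table: CodonFamilyTable
    environments: list[str]
    free_positions: np.ndarray  # codon indices of non-reference raw entries
    gene_ids: list[str]
    samples: np.ndarray  # (S, D)
    log_lik: np.ndarray  # (S,)
    log_post: np.ndarray  # (S,)
    meta: dict = field(default_factory=dict)

    # -- layout ------------------------------------------------------------
    @property
    def n_free(self) -> int:
        return len(self.free_positions)

    def _block(self, env: str, kind: str) -> slice:
        e = self.environments.index(env)
        off = e * 2 * self.n_free + (self.n_free if kind == "delta_eta" else 0)
        return slice(off, off + self.n_free)

    @property
    def _phi_block(self) -> slice:
        off = 2 * self.n_free * len(self.environments)
        return slice(off, off + len(self.gene_ids))

    @property
    def column_names(self) -> list[str]:
        codons = self.table.codons
        names = []
        for env in self.environments:
            names += [f"dm:{env}:{codons[i]}" for i in self.free_positions]
            names += [f"de:{env}:{codons[i]}" for i in self.free_positions]
        names += [f"logphi:{g}" for g in self.gene_ids]
        names.append("logsigma_phi")
        return names

    # -- retained window ---------------------------------------------------
    def retained_index(self, keep_frac: float | None = None) -> np.ndarray:
        keep = self.meta.get("keep_frac", 0.1) if keep_frac is None else keep_frac
        s = len(self.samples)
        return np.arange(s - max(2, int(np.ceil(keep * s))), s)

    # -- posterior summaries ----------------------------------------------
    def posterior_params(self, keep_frac: float | None = None) -> dict[str, MutSelParams]:
        """Posterior-mean ΔM/Δη per environment, recentered."""
        idx = self.retained_index(keep_frac)
        mean = self.samples[idx].mean(axis=0)
        out = {}
        for env in self.environments:
            dm = np.zeros(self.table.n_codons)
            de = np.zeros(self.table.n_codons)
            dm[self.free_positions] = mean[self._block(env, "delta_m")]
            de[self.free_positions] = mean[self._block(env, "delta_eta")]
            out[env] = MutSelParams(self.table, dm, de, env).recenter()
        return out

    def posterior_phi(
        self, keep_frac: float | None = None, renormalize: bool = True
    ) -> pd.Series:
        """Posterior-mean φ per gene, renormalized to mean exactly 1.

        ``renormalize=False`` returns the raw posterior mean, which is the
        self-consistent companion of the posterior-mean Δη (rescaling φ
        without rescaling Δη changes the likelihood).
        """
        idx = self.retained_index(keep_frac)
        phi = np.exp(self.samples[idx][:, self._phi_block]).mean(axis=0)
        if renormalize:
            phi = phi / phi.mean()
        return pd.Series(phi, index=self.gene_ids, name="phi")

    def posterior_sigma_phi(self, keep_frac: float | None = None) -> float:
        idx = self.retained_index(keep_frac)
        return float(np.exp(self.samples[idx][:, -1]).mean())

    def summary_frame(self, keep_frac: float | None = None) -> pd.DataFrame:
        """Per-codon posterior mean and central 95% interval, recentered."""
        idx = self.retained_index(keep_frac)
        rows = []
        for env in self.environments:
            for kind in ("delta_m", "delta_eta"):
                block = self.samples[idx][:, self._block(env, kind)]
                full = np.zeros((len(idx), self.table.n_codons))
                full[:, self.free_positions] = block
                for fam in self.table.families:
                    cols = self.table.slice(fam.label)
                    centered = full[:, cols] - full[:, cols].mean(axis=1, keepdims=True)
                    for j, codon in enumerate(fam.codons):
                        rows.append(
                            {
                                "environment": env,
                                "kind": kind,
                                "family": fam.label,
                                "codon": codon,
                                "mean": centered[:, j].mean(),
                                "q2.5": np.quantile(centered[:, j], 0.025),
                                "q97.5": np.quantile(centered[:, j], 0.975),
                            }
                        )
        return pd.DataFrame(rows)

    # -- io ----------------------------------------------------------------
    def to_tsv(self, path) -> None:
        frame = pd.DataFrame(self.samples, columns=self.column_names)
        frame.insert(0, "log_post", self.log_post)
        frame.insert(0, "log_lik", self.log_lik)
        frame.insert(0, "sample", np.arange(len(frame)))
        frame.to_csv(path, sep="\t", index=False)
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(
                {
                    "environments": self.environments,
                    "free_positions": self.free_positions.tolist(),
                    "gene_ids": self.gene_ids,
                    "genetic_code": self.table.genetic_code,
                    "meta": _jsonable(self.meta),
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_tsv(cls, path) -> "PosteriorTrace":
        with open(str(path) + ".meta.json") as fh:
            info = json.load(fh)
        table = CodonFamilyTable.for_code(info["genetic_code"])
        frame = pd.read_csv(path, sep="\t")
        return cls(
            table=table,
            environments=info["environments"],
            free_positions=np.array(info["free_positions"], dtype=int),
            gene_ids=info["gene_ids"],
            samples=frame.iloc[:, 3:].to_numpy(),
            log_lik=frame["log_lik"].to_numpy(),
            log_post=frame["log_post"].to_numpy(),
            meta=info["meta"],
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction of a scalar chain."""
    x = np.asarray(x, dtype=float)
    n = len(x) // 2
    if n < 2:
        return np.nan
    halves = np.stack([x[:n], x[len(x) - n :]])
    w = halves.var(axis=1, ddof=1).mean()
    b = n * halves.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0
    return float(np.sqrt(((n - 1) / n * w + b / n) / w))


# ---------------------------------------------------------------------------
# sampler internals


class _Sampler:
    """Metropolis-within-Gibbs state and kernels over sufficient statistics.

    Codons are family-blocked in the global ordering, so per-family
    log-sum-exps and count sums reduce to ``np.*.reduceat`` segment
    operations — no per-family Python loops in the likelihood.
    """

    def __init__(self, genome: GenomeCounts, env_of_gene, n_env, est, rng):
        table = genome.table
        self.table = table
        self.est = est
        self.rng = rng
        self.N = genome.matrix()
        self.G, self.C = self.N.shape
        self.fam_idx = [table.slice(f.label) for f in table.families]
        self.F = len(self.fam_idx)
        self.starts = np.array([idx[0] for idx in self.fam_idx])
        self.sizes = np.array([len(idx) for idx in self.fam_idx])
        self.M = np.add.reduceat(self.N, self.starts, axis=1)
        self.env_rows = [np.flatnonzero(env_of_gene == e) for e in range(n_env)]
        self.E = n_env
        self.free = np.concatenate([idx[1:] for idx in self.fam_idx])
        self.free_fam = np.repeat(np.arange(self.F), self.sizes - 1)
        self.free_starts = np.concatenate([[0], np.cumsum(self.sizes - 1)])[:-1]
        self.n_free = len(self.free)

        # state (filled by init_state)
        self.dm = np.zeros((n_env, self.C))
        self.de = np.zeros((n_env, self.C))
        self.logphi = np.zeros(self.G)
        self.logsigma = 0.0
        self.L = np.zeros((self.G, self.F))  # per-gene per-family loglik

        # adaptive proposal scales; family moves come in two flavours:
        # 0 = ΔM-only, 1 = "ridge" (δΔη = ε, δΔM = −ε, ΔM + Δη fixed) —
        # the latter walks along the weakly identified direction at φ ≈ 1
        self.fam_scale = np.full((n_env, self.F, 2), 0.1)
        self.phi_scale = np.full(self.G, 0.5)
        self.sig_scale = 0.1
        self.rescale_scale = 0.1
        self.acc = {"family": [0, 0], "phi": [0, 0], "sigma_phi": [0, 0]}
        self._win = [np.zeros((n_env, self.F, 2)), np.zeros(self.G), 0.0]

    # -- likelihood kernels ------------------------------------------------
    def _ll_rows(self, dm_e, de_e, phi_r, rows) -> np.ndarray:
        """(len(rows), F) per-gene per-family log-likelihood block."""
        logits = -(dm_e[None, :] + np.outer(phi_r, de_e))
        fmax = np.maximum.reduceat(logits, self.starts, axis=1)
        ex = np.exp(logits - np.repeat(fmax, self.sizes, axis=1))
        lse = fmax + np.log(np.add.reduceat(ex, self.starts, axis=1))
        nl = np.add.reduceat(self.N[rows] * logits, self.starts, axis=1)
        return nl - self.M[rows] * lse

    def refresh_L(self) -> None:
        phi = np.exp(self.logphi)
        for e, rows in enumerate(self.env_rows):
            self.L[rows] = self._ll_rows(self.dm[e], self.de[e], phi[rows], rows)

    # -- initialization ----------------------------------------------------
    def init_state(self, dispersed: bool) -> None:
        pooled = self.N.sum(axis=0) + 1.0
        for idx in self.fam_idx:
            self.dm[:, idx[1:]] = np.log(pooled[idx[0]] / pooled[idx[1:]])[None, :]
        self.de[:] = 0.0
        self.logsigma = float(np.log(self.est.sigma_phi_init))
        if dispersed:
            self.dm[:, self.free] += self.rng.normal(0, 0.2, (self.E, self.n_free))
            if self.est.estimate_selection:
                self.de[:, self.free] = self.rng.normal(0, 0.3, (self.E, self.n_free))
            sigma = np.exp(self.logsigma)
            self.logphi = self.rng.normal(-(sigma**2) / 2, sigma, self.G)
        else:
            self.logphi = np.zeros(self.G)
        self.refresh_L()

    def state(self):
        return (
            self.dm.copy(),
            self.de.copy(),
            self.logphi.copy(),
            self.logsigma,
            self.L.copy(),
            self.fam_scale.copy(),
            self.phi_scale.copy(),
            self.sig_scale,
        )

    def set_state(self, state) -> None:
        (self.dm, self.de, self.logphi, self.logsigma, self.L,
         self.fam_scale, self.phi_scale, self.sig_scale) = [
            s.copy() if isinstance(s, np.ndarray) else s for s in state
        ]

    # -- posterior pieces --------------------------------------------------
    def log_prior(self) -> float:
        est = self.est
        sigma = np.exp(self.logsigma)
        v = est.prior_sd**2
        lp = -(
            np.sum(self.dm[:, self.free] ** 2) + np.sum(self.de[:, self.free] ** 2)
        ) / (2 * v)
        mu = -(sigma**2) / 2
        lp += np.sum(-0.5 * ((self.logphi - mu) / sigma) ** 2 - np.log(sigma))
        lp += -(sigma**2) / (2 * est.sigma_phi_prior_scale**2) + self.logsigma
        return float(lp)

    def log_lik(self) -> float:
        return float(self.L.sum())

    def log_post(self) -> float:
        return self.log_lik() + self.log_prior()

    def theta(self) -> np.ndarray:
        return np.concatenate(
            [
                np.concatenate([self.dm[e, self.free], self.de[e, self.free]])
                for e in range(self.E)
            ]
            + [self.logphi, [self.logsigma]]
        )

    # -- one iteration -----------------------------------------------------
    def iterate(self) -> None:
        rng = self.rng
        v2 = 2 * self.est.prior_sd**2
        phi = np.exp(self.logphi)

        # (a) family-block updates, all families at once per env; a ΔM-only
        # move followed by a ridge move along the ΔM + Δη ≈ const direction
        moves = (0, 1) if self.est.estimate_selection else (0,)
        for e, rows in enumerate(self.env_rows):
            for move in moves:
                step = self.fam_scale[e, :, move][self.free_fam]
                eps = rng.normal(0, 1, self.n_free) * step
                dm_new = self.dm[e].copy()
                de_new = self.de[e].copy()
                if move == 0:
                    dm_new[self.free] += eps
                else:
                    de_new[self.free] += eps
                    dm_new[self.free] -= eps
                L_new = self._ll_rows(dm_new, de_new, phi[rows], rows)
                dll = (L_new - self.L[rows]).sum(axis=0)
                dpen = (
                    self.dm[e, self.free] ** 2 - dm_new[self.free] ** 2
                    + self.de[e, self.free] ** 2 - de_new[self.free] ** 2
                ) / v2
                dprior = np.add.reduceat(dpen, self.free_starts)
                acc_f = np.log(rng.random(self.F)) < dll + dprior
                if acc_f.any():
                    pos = self.free[acc_f[self.free_fam]]
                    self.dm[e, pos] = dm_new[pos]
                    self.de[e, pos] = de_new[pos]
                    cols = np.flatnonzero(acc_f)
                    self.L[np.ix_(rows, cols)] = L_new[:, cols]
                self.acc["family"][0] += int(acc_f.sum())
                self.acc["family"][1] += self.F
                self._win[0][e, :, move] += acc_f

        # (b) vectorized per-gene φ updates (genes conditionally independent)
        prop = self.logphi + rng.normal(0, 1, self.G) * self.phi_scale
        phi_prop = np.exp(prop)
        L_prop = np.empty_like(self.L)
        for e, rows in enumerate(self.env_rows):
            L_prop[rows] = self._ll_rows(self.dm[e], self.de[e], phi_prop[rows], rows)
        sigma = np.exp(self.logsigma)
        mu = -(sigma**2) / 2
        dpri = (-((prop - mu) ** 2) + (self.logphi - mu) ** 2) / (2 * sigma**2)
        dll = (L_prop - self.L).sum(axis=1)
        acc = np.log(rng.random(self.G)) < dll + dpri
        self.logphi[acc] = prop[acc]
        self.L[acc] = L_prop[acc]
        self.acc["phi"][0] += int(acc.sum())
        self.acc["phi"][1] += self.G
        self._win[1] += acc

        # (b2) rescale move along the exact likelihood degeneracy
        # (ΔM, Δη, φ) → (ΔM − (c−1)Δη, cΔη, 1 + (φ−1)/c): every logit is
        # unchanged, so acceptance is governed by the priors and the
        # Jacobian alone. Without this move the chain can stall in
        # collapsed-φ configurations (σ_φ → 0 with inflated Δη).
        if self.est.estimate_selection:
            c = float(np.exp(rng.normal(0, self.rescale_scale)))
            phi = np.exp(self.logphi)
            phi_new = 1.0 + (phi - 1.0) / c
            if np.all(phi_new > 0):
                logphi_new = np.log(phi_new)
                dm_new2 = self.dm - (c - 1.0) * self.de
                de_new2 = c * self.de
                # σ rides along (σ' = σ/c) so the φ spread and its prior
                # scale move together — otherwise the funnel blocks the move
                sigma = np.exp(self.logsigma)
                sigma_new = sigma / c
                logsigma_new = self.logsigma - np.log(c)
                ssc2 = 2 * self.est.sigma_phi_prior_scale**2
                mu, mu_new = -(sigma**2) / 2, -(sigma_new**2) / 2
                dprior = (
                    np.sum(self.dm[:, self.free] ** 2 - dm_new2[:, self.free] ** 2)
                    + np.sum(self.de[:, self.free] ** 2 - de_new2[:, self.free] ** 2)
                ) / v2
                dprior += np.sum(
                    ((self.logphi - mu) / sigma) ** 2
                    - ((logphi_new - mu_new) / sigma_new) ** 2
                ) / 2 + self.G * (self.logsigma - logsigma_new)
                dprior += (
                    (sigma**2 - sigma_new**2) / ssc2 + logsigma_new - self.logsigma
                )
                log_jac = (
                    self.E * self.n_free * np.log(c)
                    + np.sum(self.logphi - logphi_new) - self.G * np.log(c)
                )
                if np.log(rng.random()) < dprior + log_jac:
                    self.dm = dm_new2
                    self.de = de_new2
                    self.logphi = logphi_new
                    self.logsigma = float(logsigma_new)

        # (c) σ_φ random walk on the log scale
        prop_ls = self.logsigma + rng.normal(0, self.sig_scale)
        if np.log(rng.random()) < self._sigma_term(prop_ls) - self._sigma_term(self.logsigma):
            self.logsigma = prop_ls
            self.acc["sigma_phi"][0] += 1
            self._win[2] += 1
        self.acc["sigma_phi"][1] += 1

    def mirror_if_better(self) -> None:
        """Jump to the reflected posterior mode when it is more probable.

        The posterior has a near-exact reflection per environment:
        ΔM → ΔM + 2Δη, Δη → −Δη, φ → 2 − φ for that environment's genes
        (exact for genes with φ < 2; high-expression genes break the tie).
        During burn-in we may test the reflection directly and keep the
        better state — a deterministic initialization aid, not part of the
        stationary kernel.
        """
        for e, rows in enumerate(self.env_rows):
            cur_lp = self.log_post()
            state = self.state()
            phi_e = np.exp(self.logphi[rows])
            self.dm[e] = self.dm[e] + 2 * self.de[e]
            self.de[e] = -self.de[e]
            self.logphi[rows] = np.log(np.clip(2.0 - phi_e, 0.02, None))
            self.refresh_L()
            if self.log_post() <= cur_lp:
                self.set_state(state)

    def _sigma_term(self, logsigma: float) -> float:
        s = np.exp(logsigma)
        m = -(s**2) / 2
        return float(
            np.sum(-0.5 * ((self.logphi - m) / s) ** 2)
            - self.G * logsigma
            - (s**2) / (2 * self.est.sigma_phi_prior_scale**2)
            + logsigma
        )

    def adapt(self, window: int) -> None:
        self.fam_scale = _scale_nudge(self.fam_scale, self._win[0] / window)
        self.phi_scale = _scale_nudge(self.phi_scale, self._win[1] / window)
        self.sig_scale = float(_scale_nudge(self.sig_scale, self._win[2] / window))
        self._win[0][:] = 0
        self._win[1][:] = 0
        self._win[2] = 0.0


def _scale_nudge(scale, rate, lo=1e-4, hi=50.0):
    return np.clip(scale * np.exp(rate - _ACCEPT_TARGET), lo, hi)


# ---------------------------------------------------------------------------
# estimator


class CodonUsageModel(BaseEstimator):
    """Bayesian mutation-selection model of codon usage (MCMC estimator).

    Parameters
    ----------
    mode : {"combined", "separated"}
        ``combined`` shares one (ΔM, Δη) set across all genes; ``separated``
        gives the endogenous and exogenous gene sets their own codon
        parameters. φ is per-gene in both modes.
    iterations, thinning, burnin_frac
        MCMC length, thinning interval, and the fraction treated as burn-in
        (adaptation window for proposal scales).
    keep_frac
        Final fraction of thinned samples used for posterior summaries.
    n_starts, pilot_frac
        Number of dispersed pilot chains (each ``pilot_frac`` × iterations
        long); the state with the best log posterior seeds the main chain.
    prior_sd
        Standard deviation of the zero-mean normal prior on the raw ΔM and
        Δη entries (weakly informative).
    sigma_phi_prior_scale
        Scale of the half-normal prior on σ_φ, the spread of the lognormal
        φ prior (location −σ_φ²/2 so the prior mean of φ is 1).
    estimate_selection
        With ``False``, Δη is pinned at 0 and only mutation bias is
        estimated (φ then drops out of the likelihood); useful for
        mutation-only fits and exact low-dimensional cross-checks.
    random_state
        Seed; mandatory, recorded in the trace.

    Attributes
    ----------
    trace_ : PosteriorTrace
    params_ : dict mapping environment → recentered posterior-mean MutSelParams
    phi_ : pandas.Series of posterior-mean φ (renormalized to mean 1)
    sigma_phi_ : float
    loglik_ : log-likelihood at the posterior mean
    n_parameters_ : number of free parameters of the fitted model
    diagnostics_ : dict with split-chain R-hat and acceptance rates
    """

    def __init__(
        self,
        mode: str = COMBINED,
        iterations: int = 20_000,
        thinning: int = 50,
        burnin_frac: float = 0.5,
        keep_frac: float = 0.1,
        n_starts: int = 4,
        pilot_frac: float = 0.05,
        prior_sd: float = 10.0,
        sigma_phi_prior_scale: float = 2.0,
        sigma_phi_init: float = 1.0,
        rhat_threshold: float = 1.1,
        estimate_selection: bool = True,
        random_state: int | None = None,
    ):
        self.mode = mode
        self.iterations = iterations
        self.thinning = thinning
        self.burnin_frac = burnin_frac
        self.keep_frac = keep_frac
        self.n_starts = n_starts
        self.pilot_frac = pilot_frac
        self.prior_sd = prior_sd
        self.sigma_phi_prior_scale = sigma_phi_prior_scale
        self.sigma_phi_init = sigma_phi_init
        self.rhat_threshold = rhat_threshold
        self.estimate_selection = estimate_selection
        self.random_state = random_state

    def fit(self, genome: GenomeCounts, partition: GenomePartition | None = None):
        if self.random_state is None:
            raise ValueError("random_state (MCMC seed) is mandatory")
        if self.mode not in (COMBINED, SEPARATED):
            raise ValueError(f"unknown mode {self.mode!r}")
        rng = np.random.default_rng(self.random_state)

        if self.mode == SEPARATED:
            if partition is None:
                raise ValueError("separated mode requires a GenomePartition")
            environments = [ENDOGENOUS, EXOGENOUS]
            labels = partition.assignment.loc[genome.gene_ids]
            env_of_gene = np.where(labels == EXOGENOUS, 1, 0)
        else:
            environments = [COMBINED]
            env_of_gene = np.zeros(len(genome), dtype=int)
        for e, env in enumerate(environments):
            if np.sum(env_of_gene == e) < 2:
                raise ValueError(f"environment {env!r} has fewer than 2 genes")

        sampler = _Sampler(genome, env_of_gene, len(environments), self, rng)
        adapt_every = 50

        # pilot chains from dispersed starts pick the dominant posterior mode
        pilot_iters = max(adapt_every, int(self.pilot_frac * self.iterations))
        best = None
        for s in range(max(1, self.n_starts)):
            sampler.init_state(dispersed=s > 0)
            for it in range(1, pilot_iters + 1):
                sampler.iterate()
                if it % adapt_every == 0:
                    sampler.adapt(adapt_every)
            sampler.mirror_if_better()
            lp = sampler.log_post()
            if best is None or lp > best[0]:
                best = (lp, sampler.state())
        sampler.set_state(best[1])

        # main chain
        n_thin = self.iterations // self.thinning
        G = sampler.G
        samples = np.empty((n_thin, 2 * sampler.n_free * sampler.E + G + 1))
        log_lik = np.empty(n_thin)
        log_post = np.empty(n_thin)
        burnin = int(self.burnin_frac * self.iterations)
        for it in range(1, self.iterations + 1):
            sampler.iterate()
            if it <= burnin and it % adapt_every == 0:
                sampler.adapt(adapt_every)
                if it % (4 * adapt_every) == 0:
                    sampler.mirror_if_better()
            if it % self.thinning == 0:
                s = it // self.thinning - 1
                samples[s] = sampler.theta()
                log_lik[s] = sampler.log_lik()
                log_post[s] = log_lik[s] + sampler.log_prior()

        acceptance = {k: v[0] / max(v[1], 1) for k, v in sampler.acc.items()}
        meta = {
            "iterations": self.iterations,
            "thinning": self.thinning,
            "burnin_frac": self.burnin_frac,
            "keep_frac": self.keep_frac,
            "seed": self.random_state,
            "mode": self.mode,
            "n_starts": self.n_starts,
            "acceptance": acceptance,
        }
        trace = PosteriorTrace(
            table=genome.table,
            environments=environments,
            free_positions=sampler.free,
            gene_ids=genome.gene_ids,
            samples=samples,
            log_lik=log_lik,
            log_post=log_post,
            meta=meta,
        )
        self.trace_ = trace
        self.params_ = trace.posterior_params()
        self.phi_ = trace.posterior_phi()
        self.sigma_phi_ = trace.posterior_sigma_phi()
        self.n_parameters_ = 2 * sampler.n_free * sampler.E + G + 1
        self.environments_ = environments

        rhat = split_rhat(log_post[trace.retained_index()])
        meta["rhat_log_post"] = rhat
        self.diagnostics_ = {"rhat_log_post": rhat, **acceptance}
        if np.isfinite(rhat) and rhat > self.rhat_threshold:
            warnings.warn(
                f"MCMC may not have converged: split R-hat of the log posterior "
                f"is {rhat:.3f} (> {self.rhat_threshold})",
                stacklevel=2,
            )

        # log-likelihood at the posterior mean: recentered params (invariant)
        # with the raw posterior-mean φ (renormalization would decouple φ·Δη)
        phi_hat = trace.posterior_phi(renormalize=False).to_numpy()
        ll = 0.0
        for e, env in enumerate(environments):
            rows = sampler.env_rows[e]
            ll += sampler._ll_rows(
                self.params_[env].delta_m, self.params_[env].delta_eta, phi_hat[rows], rows
            ).sum()
        self.loglik_ = float(ll)
        return self

    def score(self, genome: GenomeCounts | None = None) -> float:
        """Log-likelihood at the posterior mean of the fitted genome."""
        return self.loglik_


def fit(
    genome: GenomeCounts,
    partition: GenomePartition | None = None,
    mode: str = COMBINED,
    **config,
) -> PosteriorTrace:
    """Functional wrapper over :class:`CodonUsageModel`; returns the trace."""
    model = CodonUsageModel(mode=mode, **config)
    model.fit(genome, partition)
    return model.trace_
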