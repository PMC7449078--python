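"""Synthetic genomes with known mutation-selection ground truth.

Generates coding sequences whose codons are drawn from the stationary model
p ∝ exp(−ΔM − Δη·φ), with per-gene protein synthesis rates φ drawn from a
mean-1 lognormal, and (optionally) two distinct cellular environments
assigned by genomic region: endogenous genes on chromosomes A/B, exogenous
genes inside a window of chromosome C. Every pipeline stage is thereby
testable against known truth without any genome download.

The bundled truth presets mirror the qualitative structure of a host genome
and an introgressed gene set: ``endogenous-like`` mutation bias favors
A/T-ending codons in ~95% of families with mixed selection preferences;
``exogenous-like`` mutation bias favors G/C-ending codons while selection
favors A/T-ending ones in ~89% of families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codon_data import Region
from .families import CodonFamilyTable
from .introgression import MU_21_DEFAULT, decay_trajectory, equilibrium_frequency
from .params import MutSelParams

DEFAULT_REGION = Region("C", 1, 989_693)


# ---------------------------------------------------------------------------
# truth presets


def _preset_params(
    table: CodonFamilyTable,
    rng: np.random.Generator,
    environment: str,
    at_mutation_fraction: float,
    at_selection_fraction: float,
    dm_scale: float = 0.5,
    de_scale: float = 0.4,
) -> MutSelParams:
    """Random recentered truth with controlled A/T- vs G/C-ending structure."""
    dm = np.zeros(table.n_codons)
    de = np.zeros(table.n_codons)
    for fam in table.families:
        idx = table.slice(fam.label)
        gc_ending = np.array([c[2] in "GC" for c in fam.codons], dtype=float)
        # bias term: +scale for the disfavored ending, −scale for the favored one
        mut_sign = 1.0 if rng.random() < at_mutation_fraction else -1.0
        sel_sign = 1.0 if rng.random() < at_selection_fraction else -1.0
        dm[idx] = mut_sign * dm_scale * (gc_ending - 0.5) + rng.normal(0, 0.25, fam.size)
        de[idx] = sel_sign * de_scale * (gc_ending - 0.5) + rng.normal(0, 0.2, fam.size)
    return MutSelParams(table, dm, de, environment).recenter()


def endogenous_like(table: CodonFamilyTable, rng: np.random.Generator) -> MutSelParams:
    """Host-like truth: mutation favors A/T endings in ~95% of families."""
    return _preset_params(table, rng, "endogenous", 0.95, 0.5)


def exogenous_like(table: CodonFamilyTable, rng: np.random.Generator) -> MutSelParams:
    """Donor-like truth: mutation favors G/C endings, selection A/T in ~89%."""
    return _preset_params(table, rng, "exogenous", 0.05, 0.89)


# ---------------------------------------------------------------------------
# truth container


@dataclass
class SimulationTruth:
    """Complete ground truth for one synthetic genome."""

    table: CodonFamilyTable
    params: dict[str, MutSelParams]  # environment -> truth
    phi: pd.Series  # per gene, mean exactly 1
    env_of_gene: pd.Series  # gene -> environment label
    lengths: pd.Series  # codons per gene (family codons)
    sigma_phi: float
    seed: int
    region: Region = field(default=DEFAULT_REGION)

    def __post_init__(self):
        if abs(self.phi.mean() - 1.0) > 1e-6:
            raise ValueError("truth φ must have mean 1")
        for env in self.env_of_gene.unique():
            if env not in self.params:
                raise ValueError(f"no truth parameters for environment {env!r}")


def make_truth(
    n_genes: int = 1000,
    n_exogenous: int = 0,
    length: int = 300,
    sigma_phi: float = 1.5,
    seed: int = 0,
    table: CodonFamilyTable | None = None,
    params: dict[str, MutSelParams] | None = None,
    region: Region = DEFAULT_REGION,
) -> SimulationTruth:
    """Assemble a :class:`SimulationTruth` from presets (or given parameters).

    φ is lognormal with location −σ_φ²/2 (prior mean 1) and renormalized to
    mean exactly 1 after sampling. With ``n_exogenous > 0`` the last genes
    are placed in the exogenous environment inside the genomic window.
    """
    if table is None:
        table = CodonFamilyTable.standard()
    rng = np.random.default_rng(seed)
    if params is None:
        params = {"endogenous": endogenous_like(table, rng)}
        if n_exogenous > 0:
            params["exogenous"] = exogenous_like(table, rng)
    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    phi = rng.lognormal(-(sigma_phi**2) / 2, sigma_phi, n_genes)
    phi = phi / phi.mean()
    envs = ["endogenous"] * (n_genes - n_exogenous) + ["exogenous"] * n_exogenous
    return SimulationTruth(
        table=table,
        params=params,
        phi=pd.Series(phi, index=gene_ids, name="phi"),
        env_of_gene=pd.Series(envs, index=gene_ids, name="environment"),
        lengths=pd.Series(length, index=gene_ids, name="length"),
        sigma_phi=sigma_phi,
        seed=seed,
        region=region,
    )


# ---------------------------------------------------------------------------
# genome simulation


def _annotation(truth: SimulationTruth, rng: np.random.Generator) -> pd.DataFrame:
    """Place endogenous genes on chromosomes A/B, exogenous inside the window."""
    rows = []
    endo_i = exo_i = 0
    window = truth.region
    for gene_id, env in truth.env_of_gene.items():
        if env == "exogenous":
            start = window.start + (exo_i * 2000) % max(1, window.end - window.start - 1000)
            rows.append({"gene_id": gene_id, "chromosome": window.chromosome, "start": start})
            exo_i += 1
        else:
            chrom = "A" if endo_i % 2 == 0 else "B"
            rows.append({"gene_id": gene_id, "chromosome": chrom, "start": 1 + 2000 * (endo_i // 2)})
            endo_i += 1
    return pd.DataFrame(rows).set_index("gene_id")


def simulate_genome(
    truth: SimulationTruth, outdir: str | Path | None = None
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Draw coding sequences under the stationary model.

    For each gene, amino-acid usage is multinomial over the 19 families
    (uniform composition by default), codons are drawn independently from the
    stationary probabilities at the gene's φ, the codon order is shuffled,
    and an ATG start plus TAA stop are appended. Returns ``(records,
    annotation)`` where records are (id, sequence) pairs; with ``outdir`` the
    FASTA, annotation TSV and truth tables are also written there.
    Byte-identical output for identical truth (seeded from ``truth.seed``).
    """
    table = truth.table
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 1]))
    n_fam = len(table.families)
    records = []
    for gene_id in truth.phi.index:
        env = truth.env_of_gene.loc[gene_id]
        par = truth.params[env]
        phi_g = float(truth.phi.loc[gene_id])
        length = int(truth.lengths.loc[gene_id])
        m = rng.multinomial(length, np.full(n_fam, 1.0 / n_fam))
        codons: list[str] = []
        for fam, m_f in zip(table.families, m):
            if m_f == 0:
                continue
            idx = table.slice(fam.label)
            logits = -(par.delta_m[idx] + par.delta_eta[idx] * phi_g)
            logits -= logits.max()
            p = np.exp(logits)
            draws = rng.multinomial(m_f, p / p.sum())
            for codon, k in zip(fam.codons, draws):
                codons.extend([codon] * k)
        order = rng.permutation(len(codons))
        seq = "ATG" + "".join(codons[i] for i in order) + "TAA"
        records.append((gene_id, seq))
    annotation = _annotation(truth, rng)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "genome.fasta", "w") as fh:
            for gene_id, seq in records:
                fh.write(f">{gene_id}\n")
                for k in range(0, len(seq), 70):
                    fh.write(seq[k : k + 70] + "\n")
        annotation.to_csv(outdir / "annotation.tsv", sep="\t", header=False)
        truth.phi.to_csv(outdir / "truth_phi.tsv", sep="\t")
        truth.env_of_gene.to_csv(outdir / "truth_environment.tsv", sep="\t")
        for env, par in truth.params.items():
            par.to_tsv(outdir / f"truth_params_{env}.tsv")
    return records, annotation


def simulate_counts(truth: SimulationTruth) -> "GenomeCounts":
    """Draw per-gene codon counts directly (no sequence construction).

    Distributionally identical to counting the FASTA from
    :func:`simulate_genome` (amino-acid usage multinomial over families,
    codons multinomial within family at the gene's φ), but much faster —
    the codon counts are the model's sufficient statistics. Uses an
    independent random stream derived from ``truth.seed``.
    """
    from .codon_data import GenomeCounts

    table = truth.table
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 2]))
    n_fam = len(table.families)
    rows = np.zeros((len(truth.phi), table.n_codons), dtype=np.int64)
    for g, gene_id in enumerate(truth.phi.index):
        par = truth.params[truth.env_of_gene.loc[gene_id]]
        phi_g = float(truth.phi.loc[gene_id])
        m = rng.multinomial(int(truth.lengths.loc[gene_id]), np.full(n_fam, 1.0 / n_fam))
        for fam, m_f in zip(table.families, m):
            if m_f == 0:
                continue
            idx = table.slice(fam.label)
            logits = -(par.delta_m[idx] + par.delta_eta[idx] * phi_g)
            logits -= logits.max()
            p = np.exp(logits)
            rows[g, idx] = rng.multinomial(m_f, p / p.sum())
    counts = pd.DataFrame(rows, index=list(truth.phi.index), columns=list(table.codons))
    counts.index.name = "gene_id"
    annotation = _annotation(truth, rng)
    return GenomeCounts(table, counts, annotation)


# ---------------------------------------------------------------------------
# decayed introgression


def simulate_decayed_introgression(
    source: MutSelParams,
    host: MutSelParams,
    age: float,
    mu_21: float = MU_21_DEFAULT,
    include_z: bool = True,
) -> MutSelParams:
    """Exogenous ΔM after ``age`` generations of decay toward the host.

    Each two-codon family's codon-1 frequency starts at the source lineage's
    mutation equilibrium and relaxes toward the host's; the decayed frequency
    is converted back to a recentered pairwise contrast. Families with more
    than two codons keep the source values unchanged. Δη is copied from the
    source (the clock models mutation only).
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    src = source.recenter()
    hst = host.recenter()
    dm = src.delta_m.copy()
    for fam in src.table.two_codon_families(include_z):
        idx = src.table.slice(fam.label)
        c0 = equilibrium_frequency(dm[idx][0] - dm[idx][1])
        host_contrast = hst.delta_m[idx][0] - hst.delta_m[idx][1]
        c_t = decay_trajectory(c0, host_contrast, mu_21, age)
        contrast_t = float(np.log((1.0 - c_t) / c_t))
        dm[idx] = [contrast_t / 2, -contrast_t / 2]
    return MutSelParams(src.table, dm, src.delta_eta.copy(), "exogenous").recenter()
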