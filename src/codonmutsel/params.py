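"""Per-codon mutation-bias and selection-bias parameter sets.

A :class:`MutSelParams` holds, for one cellular environment (one genome or
gene set), the per-codon mutation bias ΔM and selection bias Δη of the
stationary codon model p ∝ exp(−ΔM − Δη·φ). Because only within-family
contrasts are identifiable, parameters are reported *recentered*: each value
expressed as its deviation from the family mean, so the choice of reference
codon cannot reorganise families relative to each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .families import CodonFamilyTable

_RECENTER_TOL = 1e-8


@dataclass
class MutSelParams:
    """Mutation bias (ΔM) and selection bias (Δη) per codon for one environment.

    Parameters
    ----------
    table
        Codon family table the values are defined over.
    delta_m, delta_eta
        Arrays aligned with ``table.codons``. Dimensionless; Δη is the
        fitness difference between synonymous codons scaled by 2·N_e·q for a
        gene of average expression (φ = 1).
    environment
        Free-text label, e.g. ``"endogenous"``.
    """

    table: CodonFamilyTable
    delta_m: np.ndarray
    delta_eta: np.ndarray
    environment: str = ""

    def __post_init__(self):
        self.delta_m = np.asarray(self.delta_m, dtype=float)
        self.delta_eta = np.asarray(self.delta_eta, dtype=float)
        n = self.table.n_codons
        if self.delta_m.shape != (n,) or self.delta_eta.shape != (n,):
            raise ValueError(
                f"parameter arrays must have shape ({n},) to match the family table"
            )
        if not (np.isfinite(self.delta_m).all() and np.isfinite(self.delta_eta).all()):
            raise ValueError("non-finite parameter values")

    # -- recentering -------------------------------------------------------
    def recenter(self) -> "MutSelParams":
        """Return a copy with each value expressed relative to its family mean."""
        dm = self.delta_m.copy()
        de = self.delta_eta.copy()
        for fam in self.table.families:
            idx = self.table.slice(fam.label)
            dm[idx] -= dm[idx].mean()
            de[idx] -= de[idx].mean()
        return MutSelParams(self.table, dm, de, self.environment)

    @property
    def is_recentered(self) -> bool:
        for fam in self.table.families:
            idx = self.table.slice(fam.label)
            if abs(self.delta_m[idx].sum()) > _RECENTER_TOL * max(1, fam.size):
                return False
            if abs(self.delta_eta[idx].sum()) > _RECENTER_TOL * max(1, fam.size):
                return False
        return True

    # -- accessors ---------------------------------------------------------
    def family_values(self, label: str, kind: str = "delta_m") -> np.ndarray:
        idx = self.table.slice(label)
        return getattr(self, kind)[idx]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fam in self.table.families:
            for codon in fam.codons:
                i = self.table.codon_position(codon)
                rows.append(
                    {
                        "codon": codon,
                        "family": fam.label,
                        "amino_acid": fam.amino_acid,
                        "delta_m": self.delta_m[i],
                        "delta_eta": self.delta_eta[i],
                        "environment": self.environment,
                    }
                )
        return pd.DataFrame(rows)

    # -- io ----------------------------------------------------------------
    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, table: CodonFamilyTable, environment: str | None = None
    ) -> "MutSelParams":
        frame = frame.set_index("codon")
        dm = np.empty(table.n_codons)
        de = np.empty(table.n_codons)
        for i, codon in enumerate(table.codons):
            if codon not in frame.index:
                raise ValueError(f"parameter table missing codon {codon}")
            dm[i] = frame.at[codon, "delta_m"]
            de[i] = frame.at[codon, "delta_eta"]
        if environment is None:
            env = frame["environment"].iloc[0] if "environment" in frame else ""
        else:
            env = environment
        return cls(table, dm, de, env)

    @classmethod
    def from_tsv(
        cls, path, table: CodonFamilyTable, environment: str | None = None
    ) -> "MutSelParams":
        return cls.from_frame(pd.read_csv(path, sep="\t"), table, environment)
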