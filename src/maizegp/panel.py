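"""Core in-memory containers shared across the pipeline.

A :class:`GenotypePanel` holds a lines x markers dosage matrix (0/1/2 counts
of the alternate allele, ``nan`` for missing) together with the marker map
(chromosome, 1-based physical position).  Inbred panels are expected to be
homozygous (dosages 0/2 only) but heterozygous calls are accepted everywhere.

Phenotypes travel as long-format :class:`pandas.DataFrame` objects with
columns ``line, environment, replicate, block, trait, value`` (see
:func:`validate_phenotypes`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PHENOTYPE_COLUMNS = ["line", "environment", "replicate", "block", "trait", "value"]


class PanelError(ValueError):
    """Raised when a genotype panel violates its structural invariants."""


@dataclass
class GenotypePanel:
    """Lines x markers dosage matrix with a physical marker map.

    Attributes
    ----------
    line_ids : list of str
        Unique line identifiers, one per row of ``dosage``.
    marker_ids : list of str
        Unique marker identifiers, one per column of ``dosage``.
    chromosome : np.ndarray of str
        Chromosome label per marker.
    position_bp : np.ndarray of int
        1-based physical position per marker, strictly increasing within
        each chromosome.
    dosage : np.ndarray of float
        Alternate-allele counts in {0, 1, 2}; ``nan`` marks a missing call.
    subpopulation : list of str, optional
        Per-line subpopulation label (e.g. from a structured simulation).
    """

    line_ids: list[str]
    marker_ids: list[str]
    chromosome: np.ndarray
    position_bp: np.ndarray
    dosage: np.ndarray
    subpopulation: list[str] | None = None

    def __post_init__(self) -> None:
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.validate()

    # -- structural checks -------------------------------------------------
    def validate(self) -> None:
        n, m = self.dosage.shape
        if len(self.line_ids) != n:
            raise PanelError(f"{len(self.line_ids)} line ids for {n} dosage rows")
        if len(self.marker_ids) != m:
            raise PanelError(f"{len(self.marker_ids)} marker ids for {m} dosage columns")
        if len(set(self.line_ids)) != n:
            raise PanelError("duplicate line ids")
        if len(set(self.marker_ids)) != m:
            raise PanelError("duplicate marker ids")
        if self.chromosome.shape != (m,) or self.position_bp.shape != (m,):
            raise PanelError("marker map length mismatch")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise PanelError("dosages must be in {0, 1, 2} or nan")
        for chrom in pd.unique(self.chromosome):
            pos = self.position_bp[self.chromosome == chrom]
            if np.any(np.diff(pos) <= 0):
                raise PanelError(f"positions not strictly increasing on {chrom}")
        if self.subpopulation is not None and len(self.subpopulation) != n:
            raise PanelError("subpopulation labels must match line count")

    # -- convenience -------------------------------------------------------
    @property
    def n_lines(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per marker."""
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    def allele_frequency(self) -> np.ndarray:
        """Observed alternate-allele frequency per marker (non-missing calls)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def minor_allele_frequency(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def subset(self, line_idx=None, marker_idx=None) -> "GenotypePanel":
        """Return a new panel restricted to the given line/marker indices."""
        line_idx = np.arange(self.n_lines) if line_idx is None else np.asarray(line_idx)
        marker_idx = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        sub = None
        if self.subpopulation is not None:
            sub = [self.subpopulation[i] for i in line_idx]
        return GenotypePanel(
            line_ids=[self.line_ids[i] for i in line_idx],
            marker_ids=[self.marker_ids[j] for j in marker_idx],
            chromosome=self.chromosome[marker_idx],
            position_bp=self.position_bp[marker_idx],
            dosage=self.dosage[np.ix_(line_idx, marker_idx)],
            subpopulation=sub,
        )

    def copy(self) -> "GenotypePanel":
        return GenotypePanel(
            line_ids=list(self.line_ids),
            marker_ids=list(self.marker_ids),
            chromosome=self.chromosome.copy(),
            position_bp=self.position_bp.copy(),
            dosage=self.dosage.copy(),
            subpopulation=None if self.subpopulation is None else list(self.subpopulation),
        )


@dataclass
class KinshipMatrix:
    """Symmetric lines x lines relationship matrix with a method tag."""

    line_ids: list[str]
    values: np.ndarray
    method: str = "IBS"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise PanelError("kinship shape does not match line ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise PanelError("kinship matrix not symmetric")

    def align(self, line_ids: list[str]) -> np.ndarray:
        """Return the sub-matrix for ``line_ids`` in that order."""
        index = {l: i for i, l in enumerate(self.line_ids)}
        try:
            idx = np.array([index[l] for l in line_ids])
        except KeyError as exc:  # pragma: no cover - defensive
            raise PanelError(f"line {exc.args[0]!r} absent from kinship") from exc
        return self.values[np.ix_(idx, idx)]


def validate_phenotypes(records: pd.DataFrame, require_design: bool = False) -> pd.DataFrame:
    """Check a long-format phenotype table and return it with canonical columns.

    Enforces uniqueness of the (line, environment, replicate, trait) key and
    finiteness of values.  ``require_design`` additionally demands replicate
    and block labels (needed by the phenotypic adjustment model).
    """
    missing = [c for c in ("line", "environment", "trait", "value") if c not in records.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns {missing}")
    rec = records.copy()
    if "replicate" not in rec.columns:
        if require_design:
            raise ValueError("phenotype table lacks replicate labels")
        rec["replicate"] = 1
    if "block" not in rec.columns:
        if require_design:
            raise ValueError("phenotype table lacks block labels")
        rec["block"] = 1
    if not np.isfinite(rec["value"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite phenotype values")
    key = ["line", "environment", "replicate", "trait"]
    dup = rec.duplicated(subset=key)
    if dup.any():
        first = rec.loc[dup, key].iloc[0].tolist()
        raise ValueError(f"duplicate phenotype key {first}")
    return rec[PHENOTYPE_COLUMNS]
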