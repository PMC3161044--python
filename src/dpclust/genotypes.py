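"""Multilocus genotype tables in a STRUCTURE-style plain-text format.

A genotype table holds ``n`` individuals typed at ``L`` unlinked loci.  Each
diploid genotype occupies two integer allele slots whose order carries no
meaning; haploid data use a single slot.  Allele labels found on disk are
recoded to dense 0-based codes per locus (first-seen order), keeping the
original labels for lossless round-tripping.  Missing allele copies are
stored as :data:`MISSING` and contribute nothing to allele counts or
likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing allele copy (internal dense coding).
MISSING = -1


class GenotypeParseError(ValueError):
    """Raised for malformed genotype files (names the offending line)."""


@dataclass
class GenotypeTable:
    """Dense-coded genotypes: ``alleles[i, l, s]`` is allele slot ``s`` of
    individual ``i`` at locus ``l`` (``MISSING`` if not observed).

    Slot order is normalised so a missing copy always occupies the last
    slot; the two slots of a diploid genotype are unordered.
    """

    alleles: np.ndarray
    individuals: list[str] = field(default_factory=list)
    locus_names: list[str] = field(default_factory=list)
    allele_labels: list[list[str]] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.alleles, dtype=np.int64)
        if a.ndim != 3 or a.shape[2] not in (1, 2):
            raise ValueError("alleles must have shape (n, L, ploidy) with ploidy 1 or 2")
        if a.shape[0] < 1 or a.shape[1] < 1:
            raise ValueError("empty genotype table: need at least one individual and one locus")
        if a.shape[2] == 2:
            # missing copy goes to the second slot (slot order is meaningless)
            swap = (a[:, :, 0] == MISSING) & (a[:, :, 1] != MISSING)
            a[swap] = a[swap][:, ::-1]
        self.alleles = a
        if not self.individuals:
            self.individuals = [f"ind{i}" for i in range(a.shape[0])]
        if not self.locus_names:
            self.locus_names = [f"locus{l}" for l in range(a.shape[1])]
        if len(self.individuals) != a.shape[0] or len(self.locus_names) != a.shape[1]:
            raise ValueError("label lengths do not match allele array")

    # -- basic shape -----------------------------------------------------
    @property
    def n(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    @property
    def ploidy(self) -> int:
        return self.alleles.shape[2]

    @property
    def n_alleles(self) -> np.ndarray:
        """J_l: number of distinct observed alleles per locus (>= 1)."""
        return np.maximum(self.alleles.max(axis=(0, 2)), 0) + 1

    def allele_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Return the two slot arrays ``(a1, a2)`` of shape (n, L).

        For haploid tables ``a2`` is all-missing, which makes every
        downstream likelihood degenerate to the single-copy predictive.
        """
        a1 = np.ascontiguousarray(self.alleles[:, :, 0])
        if self.ploidy == 1:
            a2 = np.full_like(a1, MISSING)
        else:
            a2 = np.ascontiguousarray(self.alleles[:, :, 1])
        return a1, a2

    def subset(self, individuals=None, loci=None) -> "GenotypeTable":
        ind = np.arange(self.n) if individuals is None else np.asarray(individuals)
        loc = np.arange(self.n_loci) if loci is None else np.asarray(loci)
        labels = None
        if self.allele_labels is not None:
            labels = [self.allele_labels[l] for l in loc]
        return GenotypeTable(
            self.alleles[np.ix_(ind, loc)],
            [self.individuals[i] for i in ind],
            [self.locus_names[l] for l in loc],
            labels,
        )


@dataclass
class LocusSummary:
    """Per-locus allele summaries: J_l, frequencies, monomorphic flags."""

    n_alleles: np.ndarray
    frequencies: list[np.ndarray]
    monomorphic: np.ndarray
    observed_heterozygosity: np.ndarray | None
    mean_observed_heterozygosity: float | None

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "n_alleles": self.n_alleles,
            "monomorphic": self.monomorphic,
            "frequencies": [",".join(f"{p:.6g}" for p in f) for f in self.frequencies],
        }
        if self.observed_heterozygosity is not None:
            rows["observed_heterozygosity"] = self.observed_heterozygosity
        return pd.DataFrame(rows)


def read_genotype_table(
    path,
    missing_code: int = -9,
    ploidy: int = 2,
    two_rows_per_individual: bool = False,
) -> GenotypeTable:
    """Read a whitespace-delimited genotype file.

    Default dialect: one row per individual — a label followed by
    ``ploidy * L`` integer allele columns (the two copies of a locus in
    adjacent columns).  With ``two_rows_per_individual`` the STRUCTURE
    dialect of two rows of ``L`` columns per diploid individual is
    accepted and converted losslessly.
    """
    if ploidy not in (1, 2):
        raise ValueError("ploidy must be 1 or 2")
    rows: list[tuple[str, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            rows.append((parts[0], parts[1:]))
            if len(parts) < 2:
                raise GenotypeParseError(f"line {lineno}: no genotype columns")
    if not rows:
        raise GenotypeParseError("empty genotype file")

    if two_rows_per_individual and ploidy == 2:
        if len(rows) % 2:
            raise GenotypeParseError("two-row dialect: odd number of rows")
        merged = []
        for k in range(0, len(rows), 2):
            (lab1, r1), (lab2, r2) = rows[k], rows[k + 1]
            if len(r1) != len(r2):
                raise GenotypeParseError(
                    f"line {k + 2}: row pair for '{lab1}' has unequal column counts"
                )
            inter = [v for pair in zip(r1, r2) for v in pair]
            merged.append((lab1, inter))
        rows = merged

    n_cols = len(rows[0][1])
    if n_cols % ploidy:
        raise GenotypeParseError(f"line 1: {n_cols} allele columns not divisible by ploidy {ploidy}")
    n_loci = n_cols // ploidy
    labels = []
    raw = np.empty((len(rows), n_loci, ploidy), dtype=np.int64)
    for i, (lab, cols) in enumerate(rows):
        if len(cols) != n_cols:
            raise GenotypeParseError(
                f"line {i + 1}: expected {n_cols} allele columns, found {len(cols)}"
            )
        labels.append(lab)
        try:
            vals = [int(c) for c in cols]
        except ValueError as exc:
            raise GenotypeParseError(f"line {i + 1}: non-integer allele code") from exc
        raw[i] = np.asarray(vals, dtype=np.int64).reshape(n_loci, ploidy)

    # dense recode per locus, first-seen order
    coded = np.full_like(raw, MISSING)
    allele_labels: list[list[str]] = []
    for l in range(n_loci):
        seen: dict[int, int] = {}
        for i in range(len(rows)):
            for s in range(ploidy):
                v = raw[i, l, s]
                if v == missing_code:
                    continue
                if v not in seen:
                    seen[v] = len(seen)
                coded[i, l, s] = seen[v]
        allele_labels.append([str(v) for v in seen])
    return GenotypeTable(coded, labels, [f"locus{l}" for l in range(n_loci)], allele_labels)


def write_genotype_table(table: GenotypeTable, path, missing_code: int = -9) -> None:
    """Write the one-row-per-individual dialect, restoring original allele
    labels when the table carries a recode map."""
    with open(path, "w") as fh:
        for i in range(table.n):
            cells = [table.individuals[i]]
            for l in range(table.n_loci):
                for s in range(table.ploidy):
                    v = table.alleles[i, l, s]
                    if v == MISSING:
                        cells.append(str(missing_code))
                    elif table.allele_labels is not None:
                        cells.append(table.allele_labels[l][v])
                    else:
                        cells.append(str(v))
            fh.write(" ".join(cells) + "\n")


def observed_heterozygosity(table: GenotypeTable) -> tuple[np.ndarray, float]:
    """Fraction of heterozygous genotypes per locus among genotypes with
    both copies observed, and the mean across loci."""
    if table.ploidy != 2:
        raise ValueError("observed heterozygosity requires diploid data")
    a1, a2 = table.allele_arrays()
    ok = (a1 != MISSING) & (a2 != MISSING)
    het = (a1 != a2) & ok
    with np.errstate(invalid="ignore"):
        per_locus = het.sum(axis=0) / np.maximum(ok.sum(axis=0), 1)
    per_locus = np.where(ok.sum(axis=0) > 0, per_locus, np.nan)
    return per_locus, float(np.nanmean(per_locus))


def summarize_loci(
    table: GenotypeTable, drop_monomorphic: bool = False
) -> tuple[LocusSummary, GenotypeTable]:
    """Per-locus allele counts and frequencies; optionally drop loci at
    which only one allele was observed."""
    J = table.n_alleles
    freqs = []
    for l in range(table.n_loci):
        col = table.alleles[:, l, :].ravel()
        col = col[col != MISSING]
        counts = np.bincount(col, minlength=J[l]).astype(float)
        freqs.append(counts / counts.sum())
    mono = J == 1
    if table.ploidy == 2:
        het, mean_het = observed_heterozygosity(table)
    else:
        het, mean_het = None, None
    summary = LocusSummary(J, freqs, mono, het, mean_het)
    out = table
    if drop_monomorphic:
        keep = np.flatnonzero(~mono)
        if keep.size == 0:
            raise ValueError("all loci are monomorphic; nothing left after filtering")
        out = table.subset(loci=keep)
    return summary, out
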