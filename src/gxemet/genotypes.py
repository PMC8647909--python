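"""SNP quality control, in-silico hybrids, GRM and marker principal components.

The pipeline mirrors standard practice for genotyping-by-sequencing
panels of inbred parents used to build hybrid genotypes in silico:

1. remove markers with more than two observed alleles
2. remove taxa with low site coverage or excess heterozygosity
3. remove monomorphic, high-missing/heterozygous and low-MAF markers
4. impute remaining missing calls (per-marker mode by default)
5. prune markers in high LD (sliding window on r^2 of dosages)
6. construct hybrid dosages as the parental mean, with a final MAF filter
7. compute the genomic relationship matrix G = XX'/p and marker PCs

Dosages count copies of the minor allele (0, 1, 2); missing is NaN.
The minor allele is defined on the parent panel at first computation
and frozen, so parent and hybrid codings agree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class MarkerMatrix:
    """Samples x markers minor-allele dosage matrix.

    ``dosage`` holds values in {0, 1, 2} with ``NaN`` for missing.
    ``allele_counts`` records the number of distinct alleles observed
    at each marker (needed by the biallelic filter; defaults to 2).
    Positions are 1-based and nondecreasing within chromosome.
    """

    sample_ids: list
    marker_ids: list
    dosage: np.ndarray
    chrom: np.ndarray = None
    pos: np.ndarray = None
    allele_counts: np.ndarray = None

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, p = self.dosage.shape
        if len(self.sample_ids) != n or len(self.marker_ids) != p:
            raise ValueError("id lengths inconsistent with dosage shape")
        if self.chrom is None:
            self.chrom = np.ones(p, dtype=int)
        if self.pos is None:
            self.pos = np.arange(1, p + 1)
        if self.allele_counts is None:
            self.allele_counts = np.full(p, 2, dtype=int)
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Frequency of the coded (minor) allele per marker, over non-missing calls."""
        return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def coverage(self) -> np.ndarray:
        """Per-sample fraction of non-missing calls."""
        return 1.0 - np.isnan(self.dosage).mean(axis=1)

    def het_rate(self) -> np.ndarray:
        """Per-sample fraction of heterozygous calls among non-missing."""
        het = (self.dosage == 1.0).sum(axis=1)
        nm = (~np.isnan(self.dosage)).sum(axis=1)
        return np.divide(het, nm, out=np.zeros(self.n_samples), where=nm > 0)

    def take_markers(self, idx) -> "MarkerMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            marker_ids=[self.marker_ids[i] for i in idx],
            dosage=self.dosage[:, idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            allele_counts=self.allele_counts[idx],
        )

    def take_samples(self, idx) -> "MarkerMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in idx],
            dosage=self.dosage[idx, :],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.sample_ids, columns=self.marker_ids)


@dataclass
class GRM:
    """Genomic relationship matrix G = XX'/p over samples."""

    matrix: np.ndarray
    sample_ids: list
    n_markers: int

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("GRM must be square")

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix).min())


# ---------------------------------------------------------------------------
# filters

def filter_biallelic(m: MarkerMatrix) -> MarkerMatrix:
    """Drop markers with more than two observed alleles."""
    keep = np.flatnonzero(m.allele_counts <= 2)
    log.info("biallelic filter: %d -> %d markers", m.n_markers, len(keep))
    return m.take_markers(keep)


def filter_taxa(m: MarkerMatrix, min_coverage: float = 0.70, max_het: float = 0.08) -> MarkerMatrix:
    """Drop taxa with site coverage below ``min_coverage`` or heterozygosity above ``max_het``.

    A taxon at exactly the coverage floor is retained (the rule removes
    strictly lower coverage); likewise heterozygosity strictly greater
    than the ceiling is removed.
    """
    keep = np.flatnonzero((m.coverage() >= min_coverage) & (m.het_rate() <= max_het))
    if len(keep) == 0:
        raise ValueError("all taxa removed by coverage/heterozygosity filter")
    log.info("taxa filter: %d -> %d samples", m.n_samples, len(keep))
    return m.take_samples(keep)


def filter_parent_markers(
    m: MarkerMatrix, max_missing_het: float = 0.05, maf_min: float = 0.02
) -> MarkerMatrix:
    """Drop monomorphic markers, markers missing or heterozygous in more
    than ``max_missing_het`` of lines, and markers with MAF below ``maf_min``."""
    missing_frac = np.isnan(m.dosage).mean(axis=0)
    het_frac = (m.dosage == 1.0).mean(axis=0)
    maf = m.maf()
    poly = np.array([len(np.unique(col[~np.isnan(col)])) > 1 for col in m.dosage.T])
    keep = np.flatnonzero(
        poly & (missing_frac <= max_missing_het) & (het_frac <= max_missing_het) & (maf >= maf_min)
    )
    log.info("parent marker filter: %d -> %d markers", m.n_markers, len(keep))
    return m.take_markers(keep)


def impute_missing(m: MarkerMatrix, seed: int = 0, method: str = "mode", k: int = 5) -> MarkerMatrix:
    """Impute missing dosages; observed calls are never changed.

    ``method='mode'`` (default) replaces each missing call with the
    marker's most frequent observed dosage (ties broken toward the
    smaller dosage).  ``method='knn'`` refines this by borrowing the
    mode of the ``k`` nearest samples (allele-sharing distance on
    jointly observed markers), falling back to the marker mode.
    """
    dos = m.dosage.copy()
    miss = np.isnan(dos)
    if miss.any(axis=0).any():
        fully_missing = miss.all(axis=0)
        if fully_missing.any():
            raise ValueError("fully missing marker; run filters first")
    modes = np.empty(m.n_markers)
    for j in range(m.n_markers):
        col = dos[:, j]
        obs = col[~np.isnan(col)]
        counts = {d: (obs == d).sum() for d in (0.0, 1.0, 2.0)}
        modes[j] = max(sorted(counts), key=lambda d: counts[d])
    if method == "mode":
        rows, cols = np.nonzero(miss)
        dos[rows, cols] = modes[cols]
    elif method == "knn":
        filled = np.where(miss, modes[None, :], dos)
        for i in np.flatnonzero(miss.any(axis=1)):
            d2 = np.nansum((filled - filled[i]) ** 2, axis=1)
            d2[i] = np.inf
            nn = np.argsort(d2, kind="stable")[:k]
            for j in np.flatnonzero(miss[i]):
                vals = dos[nn, j]
                vals = vals[~np.isnan(vals)]
                if len(vals):
                    counts = {d: (vals == d).sum() for d in (0.0, 1.0, 2.0)}
                    dos[i, j] = max(sorted(counts), key=lambda d: counts[d])
                else:
                    dos[i, j] = modes[j]
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    return replace(m, dosage=dos)


def _window_prune(dosage: np.ndarray, maf: np.ndarray, idx: np.ndarray, r2_max: float) -> set:
    """Return the set of (global) marker indices removed within one window."""
    removed = set()
    active = list(idx)
    while True:
        worst = None
        sub = [a for a in active if a not in removed]
        if len(sub) < 2:
            break
        X = dosage[:, sub]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(X, rowvar=False)
        r2 = np.nan_to_num(r) ** 2
        np.fill_diagonal(r2, 0.0)
        if r2.max() <= r2_max:
            break
        a, b = np.unravel_index(np.argmax(r2), r2.shape)
        ga, gb = sub[a], sub[b]
        # drop the lower-MAF member; ties -> larger column index
        if maf[ga] < maf[gb]:
            worst = ga
        elif maf[gb] < maf[ga]:
            worst = gb
        else:
            worst = max(ga, gb)
        removed.add(worst)
    return removed


def ld_prune(
    m: MarkerMatrix, window: int = 100, step: int = 5, r2_max: float = 0.99
) -> MarkerMatrix:
    """Sliding-window LD pruning on squared Pearson correlation of dosages.

    Within each window of ``window`` markers (sliding by ``step``,
    restarting at chromosome boundaries) the most correlated pair above
    ``r2_max`` is repeatedly broken by removing the lower-MAF member
    (ties: larger column index), until no pair exceeds the threshold.
    """
    if np.isnan(m.dosage).any():
        raise ValueError("LD pruning requires an imputed matrix")
    maf = m.maf()
    removed: set = set()
    for ch in np.unique(m.chrom):
        cols = np.flatnonzero(m.chrom == ch)
        start = 0
        while True:
            win = cols[start : start + window]
            if len(win) >= 2:
                live = np.array([c for c in win if c not in removed])
                if len(live) >= 2:
                    removed |= _window_prune(m.dosage, maf, live, r2_max)
            if start + window >= len(cols):
                break
            start += step
    keep = np.array([j for j in range(m.n_markers) if j not in removed])
    log.info("LD prune: %d -> %d markers", m.n_markers, len(keep))
    return m.take_markers(keep)


def build_hybrid_genotypes(
    parents: MarkerMatrix, pedigree: pd.DataFrame, maf_min: float = 0.02
) -> MarkerMatrix:
    """Construct in-silico hybrid dosages as the mean of the two parents.

    ``pedigree`` has columns ``hybrid, parent1, parent2``.  A final MAF
    filter at ``maf_min`` is applied on the hybrid panel.
    """
    index = {s: i for i, s in enumerate(parents.sample_ids)}
    rows = []
    for rec in pedigree.itertuples(index=False):
        if rec.parent1 not in index or rec.parent2 not in index:
            raise KeyError(f"pedigree references unknown parent for hybrid {rec.hybrid}")
        rows.append((parents.dosage[index[rec.parent1]] + parents.dosage[index[rec.parent2]]) / 2.0)
    dos = np.asarray(rows)
    # parental means of two homozygous parents lie in {0, 1, 2}; round
    # the rare half-dosages from residual heterozygous parent calls
    dos = np.round(dos * 2.0) / 2.0
    dos = np.clip(np.round(dos), 0.0, 2.0)
    hybrids = MarkerMatrix(
        sample_ids=list(pedigree["hybrid"]),
        marker_ids=list(parents.marker_ids),
        dosage=dos,
        chrom=parents.chrom.copy(),
        pos=parents.pos.copy(),
        allele_counts=parents.allele_counts.copy(),
    )
    keep = np.flatnonzero(hybrids.maf() >= maf_min)
    log.info("hybrid MAF filter: %d -> %d markers", hybrids.n_markers, len(keep))
    return hybrids.take_markers(keep)


# ---------------------------------------------------------------------------
# relationship matrix and principal components

def _center_scale(dosage: np.ndarray):
    """Column-center and scale to unit sample SD (ddof=1); drop zero-variance columns."""
    mu = dosage.mean(axis=0)
    sd = dosage.std(axis=0, ddof=1)
    keep = np.flatnonzero(sd > 0)
    if len(keep) == 0:
        raise ValueError("no polymorphic markers for standardization")
    return (dosage[:, keep] - mu[keep]) / sd[keep], keep


def compute_grm(m: MarkerMatrix) -> GRM:
    """G = XX'/p with X the column-centered, unit-variance dosage matrix.

    Zero-variance markers are excluded from both X and p.  The sum of
    all entries of G is ~0 because X is column-centered.
    """
    if np.isnan(m.dosage).any():
        raise ValueError("GRM requires an imputed matrix")
    x, keep = _center_scale(m.dosage)
    p = len(keep)
    g = x @ x.T / p
    return GRM(matrix=g, sample_ids=list(m.sample_ids), n_markers=p)


def marker_pcs(m: MarkerMatrix, k: int) -> pd.DataFrame:
    """First ``k`` principal-component scores of the centered/scaled dosages.

    Sign convention: within each component the loading of largest
    magnitude is made positive, so results are deterministic.
    """
    x, _ = _center_scale(m.dosage)
    n, p = x.shape
    if k > min(n - 1, p):
        raise ValueError(f"k={k} exceeds min(n-1, p)={min(n - 1, p)}")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    for j in range(k):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = u[:, :k] * s[:k]
    return pd.DataFrame(
        scores, index=m.sample_ids, columns=[f"PC{j + 1}" for j in range(k)]
    )


# ---------------------------------------------------------------------------
# I/O

def read_dosage_csv(path) -> MarkerMatrix:
    """Read a samples x markers dosage CSV (first column = sample id)."""
    df = pd.read_csv(path, index_col=0)
    return MarkerMatrix(
        sample_ids=list(df.index.astype(str)),
        marker_ids=list(df.columns.astype(str)),
        dosage=df.to_numpy(dtype=float),
    )


def write_dosage_csv(m: MarkerMatrix, path) -> None:
    m.to_frame().to_csv(path)


def read_vcf(path) -> MarkerMatrix:
    """Read genotypes from a VCF (GT field -> alt-allele dosage).

    Requires :mod:`cyvcf2`.  Alt dosage is flipped to minor-allele
    dosage per marker when the alt allele is the major one.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dosage_cols, ids, chroms, poss, ncounts = [], [], [], [], []
    for var in vcf:
        gts = np.array([g[0] + g[1] if g[0] >= 0 and g[1] >= 0 else np.nan for g in var.genotypes])
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        ncounts.append(1 + len(var.ALT))
        dosage_cols.append(gts)
    dos = np.column_stack(dosage_cols) if dosage_cols else np.empty((len(samples), 0))
    f = np.nanmean(dos, axis=0) / 2.0
    flip = f > 0.5
    dos[:, flip] = 2.0 - dos[:, flip]
    chrom_codes = pd.factorize(np.array(chroms))[0] + 1
    return MarkerMatrix(
        sample_ids=samples,
        marker_ids=ids,
        dosage=dos,
        chrom=chrom_codes,
        pos=np.array(poss),
        allele_counts=np.array(ncounts),
    )
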