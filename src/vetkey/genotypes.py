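"""Genotype containers, extraction from per-locus alignments, and SNP filtering.

The filtering chain mirrors the standard plink invocation used for
reduced-representation SNP panels: remove near-singletons by minor-allele
frequency (``--maf``), remove SNPs with excessive missingness (``--geno``),
then prune linked SNPs in a sliding window (``--indep-pairwise W S r2``).
Filters are order-dependent and each is idempotent on its own output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("vetkey")

AUTOSOMAL = "autosomal"
Z_CHROM = "Z"
CHROM_CLASSES = (AUTOSOMAL, Z_CHROM)

#: bases accepted as resolved allele calls in locus alignments
_RESOLVED = frozenset("ACGT")


@dataclass
class GenotypeMatrix:
    """Samples x bi-allelic SNPs, values in {0, 1, 2, NaN}.

    Values count copies of the designated alternate allele; NaN marks a
    missing call.  ``snp_meta`` carries one row per SNP with at least
    ``locus``, ``position`` and ``chrom_class`` columns.
    """

    values: np.ndarray
    sample_ids: list[str]
    snp_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D (samples x SNPs)")
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match genotype rows")
        if self.values.shape[1] != len(self.snp_meta):
            raise ValueError("snp_meta length does not match genotype columns")
        for col in ("locus", "position", "chrom_class"):
            if col not in self.snp_meta.columns:
                raise ValueError(f"snp_meta missing required column {col!r}")
        obs = self.values[~np.isnan(self.values)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("genotype values must be 0, 1, 2 or missing")
        self.snp_meta = self.snp_meta.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def missing_fraction(self) -> np.ndarray:
        """Per-SNP fraction of missing calls."""
        return np.isnan(self.values).mean(axis=0)

    def alt_allele_frequency(self) -> np.ndarray:
        """Per-SNP alternate-allele frequency among non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=0) / 2.0

    def minor_allele_frequency(self) -> np.ndarray:
        p = self.alt_allele_frequency()
        return np.minimum(p, 1.0 - p)

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the SNP columns in ``index`` (order kept)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            values=self.values[:, index],
            sample_ids=list(self.sample_ids),
            snp_meta=self.snp_meta.iloc[index].reset_index(drop=True),
        )

    def take_samples(self, keep_ids: list[str]) -> "GenotypeMatrix":
        order = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in keep_ids if s not in order]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        rows = [order[s] for s in keep_ids]
        return GenotypeMatrix(
            values=self.values[rows, :],
            sample_ids=list(keep_ids),
            snp_meta=self.snp_meta.copy(),
        )

    def subset_partition(self, chrom_class: str) -> "GenotypeMatrix":
        idx = np.flatnonzero((self.snp_meta["chrom_class"] == chrom_class).to_numpy())
        return self.take_snps(idx)


@dataclass
class FilterReport:
    """Bookkeeping for one or more filter stages."""

    input_snps: int
    removed: dict[str, int] = field(default_factory=dict)
    retained: int = 0

    def check(self) -> None:
        if sum(self.removed.values()) + self.retained != self.input_snps:
            raise AssertionError("filter bookkeeping identity violated")

    def merged_with(self, other: "FilterReport") -> "FilterReport":
        rem = dict(self.removed)
        for k, v in other.removed.items():
            rem[k] = rem.get(k, 0) + v
        out = FilterReport(input_snps=self.input_snps, removed=rem, retained=other.retained)
        out.check()
        return out


# ---------------------------------------------------------------------------
# SNP extraction from per-locus alignments
# ---------------------------------------------------------------------------

def extract_biallelic_snps(
    loci: dict[str, dict[str, tuple[str, str]]],
    chrom_class_by_locus: dict[str, str] | None = None,
) -> GenotypeMatrix:
    """Extract bi-allelic SNPs from per-locus two-allele alignments.

    ``loci`` maps locus id -> {sample_id: (allele_seq_1, allele_seq_2)}.
    A site enters the panel when exactly two resolved bases are observed
    across all allele copies; the rarer base (ties broken toward the
    lexicographically later base) is the alternate allele and genotypes count
    its copies.  A sample with any unresolved base at the site is missing
    there.  Loci whose sequences disagree in length are skipped with a log
    message.
    """
    sample_ids = sorted({s for aln in loci.values() for s in aln})
    sample_index = {s: i for i, s in enumerate(sample_ids)}
    columns: list[np.ndarray] = []
    meta_rows: list[dict] = []

    for locus_id in sorted(loci):
        aln = loci[locus_id]
        lengths = {len(a) for seqs in aln.values() for a in seqs}
        if len(lengths) != 1:
            logger.warning("locus %s skipped: length-mismatched alignment", locus_id)
            continue
        (length,) = lengths
        chrom = (chrom_class_by_locus or {}).get(locus_id, AUTOSOMAL)
        for pos in range(length):
            site = {s: (a1[pos].upper(), a2[pos].upper()) for s, (a1, a2) in aln.items()}
            observed = {b for pair in site.values() for b in pair if b in _RESOLVED}
            if len(observed) != 2:
                continue  # monomorphic or >2 alleles
            counts = {b: 0 for b in observed}
            for b1, b2 in site.values():
                for b in (b1, b2):
                    if b in counts:
                        counts[b] += 1
            # alternate allele = minor; lexicographically later base on ties
            alt = min(observed, key=lambda b: (counts[b], -ord(b)))
            col = np.full(len(sample_ids), np.nan)
            for s, (b1, b2) in site.items():
                if b1 in _RESOLVED and b2 in _RESOLVED:
                    col[sample_index[s]] = (b1 == alt) + (b2 == alt)
            columns.append(col)
            meta_rows.append(
                {"locus": locus_id, "position": pos, "chrom_class": chrom, "alt": alt}
            )

    values = np.column_stack(columns) if columns else np.empty((len(sample_ids), 0))
    meta = pd.DataFrame(meta_rows, columns=["locus", "position", "chrom_class", "alt"])
    return GenotypeMatrix(values=values, sample_ids=sample_ids, snp_meta=meta)


# ---------------------------------------------------------------------------
# Filtering chain
# ---------------------------------------------------------------------------

def filter_maf(gm: GenotypeMatrix, maf_min: float = 0.005) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop SNPs whose minor-allele frequency is strictly below ``maf_min``."""
    maf = gm.minor_allele_frequency()
    keep = np.flatnonzero(~(maf < maf_min))  # NaN-frequency (all-missing) SNPs kept here
    report = FilterReport(
        input_snps=gm.n_snps,
        removed={"maf": gm.n_snps - keep.size},
        retained=keep.size,
    )
    report.check()
    return gm.take_snps(keep), report


def filter_missingness(
    gm: GenotypeMatrix, max_missing: float = 0.2
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop SNPs missing in at least ``max_missing`` of samples (inclusive)."""
    frac = gm.missing_fraction()
    keep = np.flatnonzero(frac < max_missing)
    report = FilterReport(
        input_snps=gm.n_snps,
        removed={"missingness": gm.n_snps - keep.size},
        retained=keep.size,
    )
    report.check()
    return gm.take_snps(keep), report


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns over complete pairs."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return 0.0
    xs, ys = x[ok], y[ok]
    xc, yc = xs - xs.mean(), ys - ys.mean()
    vx, vy = float(xc @ xc), float(yc @ yc)
    if vx == 0.0 or vy == 0.0:
        return 0.0
    cov = float(xc @ yc)
    return cov * cov / (vx * vy)


def ld_prune(
    gm: GenotypeMatrix,
    window_snps: int = 2,
    step_snps: int = 1,
    r2_max: float = 0.5,
    seed: int = 0,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Sliding-window LD pruning on genotype dosages.

    Windows of ``window_snps`` consecutive surviving SNPs advance by
    ``step_snps``; within a window, whenever a pair has squared correlation
    strictly greater than ``r2_max`` one member is removed uniformly at
    random (seeded).  Passes repeat until no window contains such a pair, so
    the surviving panel has no window-pair above the threshold.
    """
    rng = np.random.default_rng(seed)
    alive = np.ones(gm.n_snps, dtype=bool)

    changed = True
    while changed:
        changed = False
        idx = np.flatnonzero(alive)
        start = 0
        while start + window_snps <= idx.size:
            window = idx[start : start + window_snps]
            removed_in_window = False
            for a in range(len(window)):
                for b in range(a + 1, len(window)):
                    ia, ib = window[a], window[b]
                    if not (alive[ia] and alive[ib]):
                        continue
                    r2 = _pairwise_r2(gm.values[:, ia], gm.values[:, ib])
                    if r2 > r2_max:
                        drop = ia if rng.random() < 0.5 else ib
                        alive[drop] = False
                        changed = True
                        removed_in_window = True
            if removed_in_window:
                # recompute surviving index before moving on
                idx = np.flatnonzero(alive)
                # do not advance: the refilled window must be rechecked
            else:
                start += step_snps

    keep = np.flatnonzero(alive)
    report = FilterReport(
        input_snps=gm.n_snps,
        removed={"ld": gm.n_snps - keep.size},
        retained=keep.size,
    )
    report.check()
    return gm.take_snps(keep), report


def filter_chain(
    gm: GenotypeMatrix,
    maf_min: float = 0.005,
    max_missing: float = 0.2,
    ld_window: int = 2,
    ld_step: int = 1,
    r2_max: float = 0.5,
    seed: int = 0,
) -> tuple[GenotypeMatrix, FilterReport]:
    """MAF -> missingness -> LD pruning, with a merged report."""
    g1, r1 = filter_maf(gm, maf_min)
    g2, r2 = filter_missingness(g1, max_missing)
    g3, r3 = ld_prune(g2, ld_window, ld_step, r2_max, seed)
    report = r1.merged_with(r2).merged_with(r3)
    return g3, report


# ---------------------------------------------------------------------------
# IO: genotype CSV, PED/MAP, per-locus FASTA
# ---------------------------------------------------------------------------

def write_genotype_csv(gm: GenotypeMatrix, path: str) -> None:
    df = pd.DataFrame(
        gm.values,
        index=pd.Index(gm.sample_ids, name="sample_id"),
        columns=[f"{r.locus}:{r.position}" for r in gm.snp_meta.itertuples()],
    )
    df.to_csv(path)


def read_genotype_csv(path: str, snp_meta: pd.DataFrame | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0)
    if snp_meta is None:
        loci, positions = [], []
        for col in df.columns:
            locus, _, pos = col.rpartition(":")
            loci.append(locus or col)
            positions.append(int(pos) if pos.isdigit() else 0)
        snp_meta = pd.DataFrame(
            {"locus": loci, "position": positions, "chrom_class": AUTOSOMAL}
        )
    return GenotypeMatrix(
        values=df.to_numpy(dtype=float),
        sample_ids=[str(s) for s in df.index],
        snp_meta=snp_meta,
    )


def write_ped_map(gm: GenotypeMatrix, prefix: str) -> None:
    """Write plink text PED/MAP.  Alleles coded A (ref) / B (alt), 0 missing."""
    with open(prefix + ".map", "w") as fh:
        for i, r in enumerate(gm.snp_meta.itertuples()):
            fh.write(f"0\t{r.locus}_{r.position}\t0\t{i + 1}\n")
    code = {0.0: ("A", "A"), 1.0: ("A", "B"), 2.0: ("B", "B")}
    with open(prefix + ".ped", "w") as fh:
        for s, row in zip(gm.sample_ids, gm.values):
            fields = [s, s, "0", "0", "0", "-9"]
            for g in row:
                a1, a2 = code.get(g, ("0", "0")) if not np.isnan(g) else ("0", "0")
                fields.extend((a1, a2))
            fh.write("\t".join(fields) + "\n")


def read_ped_map(prefix: str) -> GenotypeMatrix:
    map_rows = []
    with open(prefix + ".map") as fh:
        for line in fh:
            _, snp_id, _, _ = line.split()
            locus, _, pos = snp_id.rpartition("_")
            map_rows.append(
                {"locus": locus or snp_id, "position": int(pos) if pos.isdigit() else 0,
                 "chrom_class": AUTOSOMAL}
            )
    meta = pd.DataFrame(map_rows, columns=["locus", "position", "chrom_class"])
    sample_ids, rows = [], []
    with open(prefix + ".ped") as fh:
        for line in fh:
            fields = line.split()
            sample_ids.append(fields[1])
            alleles = fields[6:]
            geno = []
            for j in range(0, len(alleles), 2):
                a1, a2 = alleles[j], alleles[j + 1]
                if a1 == "0" or a2 == "0":
                    geno.append(np.nan)
                else:
                    geno.append(float((a1 == "B") + (a2 == "B")))
            rows.append(geno)
    return GenotypeMatrix(values=np.array(rows, dtype=float), sample_ids=sample_ids, snp_meta=meta)


def read_locus_fasta(paths: dict[str, str]) -> dict[str, dict[str, tuple[str, str]]]:
    """Read per-locus FASTA files into the alignment structure.

    Each FASTA holds two records per sample named ``<sample>/1`` and
    ``<sample>/2`` (or ``<sample>`` twice for homozygous convenience input).
    """
    loci: dict[str, dict[str, tuple[str, str]]] = {}
    for locus_id, path in paths.items():
        per_sample: dict[str, list[str]] = {}
        for rec in SeqIO.parse(path, "fasta"):
            sample = rec.id.rsplit("/", 1)[0]
            per_sample.setdefault(sample, []).append(str(rec.seq))
        aln = {}
        for sample, seqs in per_sample.items():
            if len(seqs) == 1:
                seqs = [seqs[0], seqs[0]]
            if len(seqs) != 2:
                raise ValueError(
                    f"locus {locus_id}: sample {sample} has {len(seqs)} allele sequences"
                )
            aln[sample] = (seqs[0], seqs[1])
        loci[locus_id] = aln
    return loci
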