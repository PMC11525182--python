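"""Cohort data model and preprocessing.

Sparse genotypes, variant-to-gene assignment, qualifying-variant filters,
the MAF annotation transform, phenotype quantile normalisation, CAF/EAF
computation and construction of the per-individual per-gene variant sets
that the impairment model consumes.

Coordinates are 1-based closed intervals throughout (VCF convention);
BED input is converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy import sparse, stats

logger = logging.getLogger("setrvat")

#: Column order of the variant-key fields in every variant table.
VARIANT_KEY_COLS = ["chrom", "pos", "ref", "alt"]

#: Boolean consequence-class flags carried by the annotation table.
CLASS_FLAG_COLS = ["is_plof", "is_missense", "is_synonymous", "is_disruptive_missense"]

#: Default qualifying-variant thresholds: association-time MAF cutoff,
#: training-time MAF cutoff, and the CADD-PHRED floor.
MAF_CUTOFF_ASSOCIATION = 0.001
MAF_CUTOFF_TRAINING = 0.01
CADD_CUTOFF = 5.0

#: Variants at most this many base pairs from an exon belong to the gene.
EXON_WINDOW_BP = 300

#: A gene is testable for a trait only if EAF = CAF * n reaches this value.
EAF_THRESHOLD = 50.0


class DataError(ValueError):
    """Malformed input data (bad intervals, unknown identifiers, ...)."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class SparseGenotypes:
    """Individuals x variants allele counts, stored sparsely.

    Only nonzero allele counts (1 = heterozygous, 2 = homozygous alternate)
    are stored.  ``maf`` holds the per-variant minor allele frequency used
    for filtering and weighting.
    """

    matrix: sparse.csr_matrix  # n_individuals x n_variants, int8
    maf: np.ndarray  # length n_variants
    individual_ids: np.ndarray  # length n_individuals, str

    def __post_init__(self) -> None:
        self.matrix = sparse.csr_matrix(self.matrix)
        self.maf = np.asarray(self.maf, dtype=float)
        self.individual_ids = np.asarray(self.individual_ids)
        if self.matrix.shape[1] != self.maf.size:
            raise DataError("MAF vector length does not match variant count")
        if self.matrix.shape[0] != self.individual_ids.size:
            raise DataError("individual id count does not match genotype rows")
        data = self.matrix.data
        if data.size and (np.any(data < 1) or np.any(data > 2)):
            raise DataError("stored allele counts must be 1 or 2")

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_variants(self) -> int:
        return self.matrix.shape[1]

    def allele_counts(self, variant_idx: np.ndarray) -> sparse.csc_matrix:
        """Dosage submatrix (individuals x selected variants), CSC for fast
        column slicing."""
        return self.matrix.tocsc()[:, variant_idx]


@dataclass
class VariantSet:
    """The unordered set of qualifying variants individual *i* carries in
    gene *j*, identified by row indices into the cohort's variant table."""

    individual: str
    gene: str
    variant_rows: np.ndarray

    def __len__(self) -> int:
        return len(self.variant_rows)


@dataclass
class CohortDataset:
    """Everything downstream stages need, with consistently keyed tables.

    ``variants`` is a DataFrame carrying the variant key columns, ``maf``,
    ``cadd_phred``, the class flags and the annotation columns named in
    ``annotation_cols`` (which include the transformed-MAF column).
    ``exons`` has columns gene_id, chrom, start, end, strand (1-based
    closed).  ``covariates`` and ``phenotypes`` are indexed by individual
    id; missing phenotype entries are NaN.
    """

    genotypes: SparseGenotypes
    variants: pd.DataFrame
    annotation_cols: list[str]
    exons: pd.DataFrame
    covariates: pd.DataFrame
    phenotypes: pd.DataFrame
    binary_traits: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = self.genotypes.individual_ids
        for tbl, name in ((self.covariates, "covariates"), (self.phenotypes, "phenotypes")):
            if not np.array_equal(np.asarray(tbl.index, dtype=ids.dtype), ids):
                raise DataError(f"{name} index does not match genotype individuals")
        missing = [c for c in self.annotation_cols if c not in self.variants.columns]
        if missing:
            raise DataError(f"annotation columns absent from variant table: {missing}")

    @property
    def gene_ids(self) -> np.ndarray:
        return self.exons["gene_id"].unique()

    @property
    def trait_names(self) -> list[str]:
        return list(self.phenotypes.columns)

    def annotation_matrix(self) -> np.ndarray:
        """Dense (n_variants x d) float matrix of model annotations."""
        return self.variants[self.annotation_cols].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# variant-to-gene assignment
# ---------------------------------------------------------------------------


def assign_variants_to_genes(
    variants: pd.DataFrame, exons: pd.DataFrame, window: int = EXON_WINDOW_BP
) -> pd.DataFrame:
    """Map variants to genes whose exons they fall in or near.

    A variant belongs to gene *j* iff its position lies within ``window``
    base pairs of any exon of *j* (distance zero inside the exon, else the
    distance to the nearer end; the window boundary is inclusive).  A
    variant may map to several genes.

    Returns a DataFrame with columns ``variant_row`` (positional index into
    ``variants``) and ``gene_id``.
    """
    if (exons["start"] > exons["end"]).any():
        bad = exons.loc[exons["start"] > exons["end"]].iloc[0]
        raise DataError(f"malformed exon interval for {bad['gene_id']}: start > end")
    out_rows: list[np.ndarray] = []
    out_genes: list[np.ndarray] = []
    pos_all = variants["pos"].to_numpy(dtype=np.int64)
    chrom_all = variants["chrom"].to_numpy()
    for chrom, ex_chr in exons.groupby("chrom", sort=False):
        on_chrom = np.flatnonzero(chrom_all == chrom)
        if on_chrom.size == 0:
            continue
        pos = pos_all[on_chrom]
        for gene_id, ex in ex_chr.groupby("gene_id", sort=False):
            starts = ex["start"].to_numpy(dtype=np.int64)
            ends = ex["end"].to_numpy(dtype=np.int64)
            # distance of each variant to each exon; 0 when inside
            d = np.maximum.reduce(
                [starts[None, :] - pos[:, None], pos[:, None] - ends[None, :],
                 np.zeros((pos.size, starts.size), dtype=np.int64)]
            )
            hit = (d.min(axis=1) <= window)
            if hit.any():
                out_rows.append(on_chrom[hit])
                out_genes.append(np.full(int(hit.sum()), gene_id, dtype=object))
    if not out_rows:
        return pd.DataFrame({"variant_row": np.array([], dtype=int), "gene_id": []})
    res = pd.DataFrame(
        {"variant_row": np.concatenate(out_rows), "gene_id": np.concatenate(out_genes)}
    )
    logger.info("assigned %d variant-gene pairs (%d distinct variants)",
                len(res), res["variant_row"].nunique())
    return res.sort_values(["gene_id", "variant_row"], ignore_index=True)


# ---------------------------------------------------------------------------
# filters and transforms
# ---------------------------------------------------------------------------


def transform_maf(p: np.ndarray | float) -> np.ndarray | float:
    """Annotation transform [p(1-p)]^(-1/2); strictly decreasing on (0, 0.5]."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise DataError("MAF transform requires frequencies strictly inside (0, 1)")
    out = 1.0 / np.sqrt(arr * (1.0 - arr))
    return float(out) if np.isscalar(p) else out


def filter_qualifying_variants(
    variants: pd.DataFrame,
    maf_cutoff: float = MAF_CUTOFF_ASSOCIATION,
    cadd_cutoff: float = CADD_CUTOFF,
) -> np.ndarray:
    """Positional indices of variants with MAF < ``maf_cutoff`` (strict) and
    CADD-PHRED > ``cadd_cutoff`` (strict)."""
    if not (0.0 < maf_cutoff < 1.0):
        raise DataError("maf_cutoff must lie in (0, 1)")
    if cadd_cutoff < 0:
        raise DataError("cadd_cutoff must be nonnegative")
    keep = (variants["maf"].to_numpy() < maf_cutoff) & (
        variants["cadd_phred"].to_numpy() > cadd_cutoff
    )
    kept = np.flatnonzero(keep)
    logger.info("qualifying-variant filter (MAF<%g, CADD>%g): kept %d / %d",
                maf_cutoff, cadd_cutoff, kept.size, len(variants))
    return kept


def quantile_transform_phenotype(y: np.ndarray | pd.Series) -> np.ndarray:
    """Rank-based inverse normal transform.

    Non-missing values are replaced by Phi^{-1}((rank - 0.5) / n) with
    average ranks for ties; NaNs stay NaN.  Monotone in the input.
    """
    arr = np.asarray(y, dtype=float)
    out = np.full(arr.shape, np.nan)
    obs = ~np.isnan(arr)
    vals = arr[obs]
    if vals.size < 2:
        raise DataError("quantile transform needs at least two non-missing values")
    if np.all(vals == vals[0]):
        raise DataError("quantile transform undefined for constant input")
    ranks = stats.rankdata(vals, method="average")
    out[obs] = stats.norm.ppf((ranks - 0.5) / vals.size)
    return out


def compute_eaf(
    qualifying_mafs: np.ndarray, n: int, threshold: float = EAF_THRESHOLD
) -> tuple[float, float, bool]:
    """Cumulative and expected allele frequency of a gene's qualifying
    variants.

    CAF is the sum of qualifying-variant MAFs; EAF = CAF * n where n is the
    cohort size for quantitative traits or the case count for binary ones.
    The gene passes iff EAF >= ``threshold`` (inclusive).
    """
    if n <= 0:
        raise DataError("cohort/case count must be positive")
    caf = float(np.sum(qualifying_mafs)) if len(qualifying_mafs) else 0.0
    eaf = caf * n
    return caf, eaf, eaf >= threshold


def build_variant_sets(
    dataset: CohortDataset,
    gene: str,
    assignment: pd.DataFrame,
    qualifying_rows: np.ndarray,
) -> list[VariantSet]:
    """Variant sets V_ij for every carrier of qualifying variants in ``gene``.

    Non-carriers implicitly hold the empty set.  Allele count 2 does not
    duplicate a variant: V_ij is a set of distinct variants (dosage stays
    available in :class:`SparseGenotypes` for the burden/SKAT tests).
    """
    if gene not in set(assignment["gene_id"]):
        raise DataError(f"unknown gene id {gene!r}")
    gene_rows = assignment.loc[assignment["gene_id"] == gene, "variant_row"].to_numpy()
    rows = np.intersect1d(gene_rows, qualifying_rows)
    if rows.size == 0:
        return []
    sub = dataset.genotypes.matrix.tocsc()[:, rows].tocsr()
    out: list[VariantSet] = []
    ids = dataset.genotypes.individual_ids
    for i in np.flatnonzero(np.diff(sub.indptr) > 0):
        carried = rows[sub.indices[sub.indptr[i]:sub.indptr[i + 1]]]
        out.append(VariantSet(individual=str(ids[i]), gene=gene, variant_rows=np.sort(carried)))
    return out


# ---------------------------------------------------------------------------
# IO: sparse container, VCF, tables
# ---------------------------------------------------------------------------

_CONTAINER_VERSION = 1


def write_sparse_genotypes(path: str, geno: SparseGenotypes) -> None:
    """Persist genotypes to a hierarchical container (CSR index arrays)."""
    csr = geno.matrix.tocsr()
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _CONTAINER_VERSION
        f.attrs["n_individuals"] = csr.shape[0]
        f.attrs["n_variants"] = csr.shape[1]
        f.create_dataset("indptr", data=csr.indptr)
        f.create_dataset("indices", data=csr.indices)
        f.create_dataset("data", data=csr.data.astype(np.int8))
        f.create_dataset("maf", data=geno.maf)
        f.create_dataset(
            "individual_ids", data=np.asarray(geno.individual_ids, dtype="S")
        )


def read_sparse_genotypes(path: str) -> SparseGenotypes:
    with h5py.File(path, "r") as f:
        if int(f.attrs["format_version"]) != _CONTAINER_VERSION:
            raise DataError("unsupported sparse-container version")
        shape = (int(f.attrs["n_individuals"]), int(f.attrs["n_variants"]))
        mat = sparse.csr_matrix(
            (f["data"][:], f["indices"][:], f["indptr"][:]), shape=shape
        )
        return SparseGenotypes(
            matrix=mat,
            maf=f["maf"][:],
            individual_ids=f["individual_ids"][:].astype(str),
        )


def write_vcf(path: str, geno: SparseGenotypes, variants: pd.DataFrame) -> None:
    """Minimal GT-only VCF of the cohort genotypes (via pysam)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                     ("Type", "String"), ("Description", "Genotype")])
    for chrom in pd.unique(variants["chrom"]):
        header.contigs.add(str(chrom))
    for ind in geno.individual_ids:
        header.add_sample(str(ind))
    csc = geno.matrix.tocsc()
    with pysam.VariantFile(path, "w", header=header) as vf:
        for k, row in enumerate(variants.itertuples(index=False)):
            rec = vf.new_record(
                contig=str(row.chrom), start=int(row.pos) - 1, stop=int(row.pos),
                alleles=(str(row.ref), str(row.alt)),
            )
            col = csc.getcol(k)
            counts = dict(zip(col.indices.tolist(), col.data.tolist()))
            for i, sample in enumerate(rec.samples.values()):
                c = counts.get(i, 0)
                sample["GT"] = (0, 0) if c == 0 else ((0, 1) if c == 1 else (1, 1))
            vf.write(rec)
    logger.info("wrote %d VCF records to %s", len(variants), path)


def read_vcf(path: str, maf: np.ndarray | None = None) -> tuple[SparseGenotypes, pd.DataFrame]:
    """Read a GT-only VCF back into sparse genotypes and a variant-key table.

    When ``maf`` is omitted the empirical alternate-allele frequency is used.
    """
    import pysam

    rows, cols, data = [], [], []
    keys = []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for k, rec in enumerate(vf):
            keys.append((rec.chrom, rec.pos, rec.ref, rec.alts[0]))
            for i, sample in enumerate(rec.samples.values()):
                c = sum(1 for a in sample["GT"] if a == 1)
                if c:
                    rows.append(i)
                    cols.append(k)
                    data.append(c)
    n, m = len(samples), len(keys)
    mat = sparse.csr_matrix((data, (rows, cols)), shape=(n, m), dtype=np.int8)
    if maf is None:
        maf = np.asarray(mat.sum(axis=0)).ravel() / (2.0 * n)
    table = pd.DataFrame(keys, columns=VARIANT_KEY_COLS)
    logger.info("read %d VCF records, %d samples from %s", m, n, path)
    return SparseGenotypes(matrix=mat, maf=maf, individual_ids=np.array(samples)), table


def read_gene_models(path: str) -> pd.DataFrame:
    """Exon table (gene_id, chrom, start, end, strand; 1-based closed) from
    GFF3 or BED."""
    import pyranges

    if path.endswith((".gff3", ".gff")):
        gr = pyranges.read_gff3(path).df
        gr = gr[gr["Feature"] == "exon"]
        gene_col = "gene_id" if "gene_id" in gr.columns else "Parent"
        out = pd.DataFrame({
            "gene_id": gr[gene_col].astype(str),
            "chrom": gr["Chromosome"].astype(str),
            # pyranges uses half-open 0-based; back to 1-based closed
            "start": gr["Start"].astype(int) + 1,
            "end": gr["End"].astype(int),
            "strand": gr.get("Strand", "+"),
        })
    elif path.endswith(".bed"):
        gr = pyranges.read_bed(path).df
        out = pd.DataFrame({
            "gene_id": gr["Name"].astype(str),
            "chrom": gr["Chromosome"].astype(str),
            "start": gr["Start"].astype(int) + 1,
            "end": gr["End"].astype(int),
            "strand": gr.get("Strand", "+"),
        })
    else:
        raise DataError(f"unrecognised gene-model format: {path}")
    logger.info("read %d exon records from %s", len(out), path)
    return out.reset_index(drop=True)


def write_gene_models_bed(path: str, exons: pd.DataFrame) -> None:
    """Write exons as BED (0-based half-open on disk)."""
    bed = pd.DataFrame({
        "chrom": exons["chrom"],
        "start": exons["start"].astype(int) - 1,
        "end": exons["end"].astype(int),
        "name": exons["gene_id"],
        "score": 0,
        "strand": exons.get("strand", "+"),
    })
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_table(path: str, index_col: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=index_col)
    logger.info("read %d records from %s", len(df), path)
    return df


def write_table(path: str, df: pd.DataFrame, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)
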