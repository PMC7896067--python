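"""Sparse per-chromosome LD correlation matrices.

LD is computed from a reference genotype panel as Pearson correlations
between standardized dosages, within chromosome only. An off-diagonal entry
``B_jk`` is retained iff the chi-squared statistic for nonzero population LD
exceeds a threshold::

    n_ref * B_jk^2 > chisq_threshold        (default 10, P < 0.0016)

which at a reference sample of 50,000 corresponds to an r^2 threshold of
2e-4. Pairs that are zeroed (or retained) contribute known LD sampling
variances to the model's residual bookkeeping (:func:`ld_sampling_variance`).

The on-disk format is a documented binary layout: an 8-byte magic string,
a JSON header (version, threshold, reference sample size, per-chromosome
block shapes), the CSR arrays of each chromosome block, and the SNP map as
a UTF-8 TSV block. :func:`export_mtx` writes standard Matrix Market text
files for debugging.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

MAGIC = b"SPLDMAT1"
FORMAT_VERSION = 1

#: Default chi-squared sparsification threshold (balances type-I/II errors).
CHISQ_DEFAULT = 10.0

MAP_COLUMNS = ["SNP", "chrom", "pos", "A1", "A2", "freq"]


def pathlib_suffix(prefix, ext: str) -> Path:
    """Append an extension to a PLINK prefix without clobbering dots in it."""
    return Path(str(prefix) + ext)


class LdError(ValueError):
    """Invalid LD input or corrupted LD file."""


@dataclass
class SparseLdMatrix:
    """Per-chromosome sparse symmetric LD correlation matrix.

    ``snp_map`` is ordered by (chrom, pos) and concatenates all chromosomes;
    ``blocks`` maps chromosome name to a CSR correlation block whose row
    order matches the map subset for that chromosome. ``nref`` is the
    (scalar) reference sample size used for the chi-squared test; with
    missing dosages pairwise-complete counts are used at build time and the
    minimum is stored.
    """

    snp_map: pd.DataFrame
    blocks: dict
    nref: float
    chisq_threshold: float = CHISQ_DEFAULT

    def __post_init__(self) -> None:
        offs, total = {}, 0
        for chrom, blk in self.blocks.items():
            offs[chrom] = total
            total += blk.shape[0]
        if total != len(self.snp_map):
            raise LdError("SNP map length does not match block sizes")
        self._offsets = offs

    @property
    def m(self) -> int:
        return len(self.snp_map)

    def neighbour_counts(self) -> np.ndarray:
        """Number of retained off-diagonal partners per SNP."""
        out = []
        for blk in self.blocks.values():
            out.append(np.asarray((blk != 0).sum(axis=1)).ravel() - 1)
        return np.concatenate(out) if out else np.zeros(0, int)

    def subset(self, ids) -> "SparseLdMatrix":
        """Restrict to the given SNP ids (kept in map order)."""
        wanted = set(ids)
        keep = self.snp_map["SNP"].isin(wanted).to_numpy()
        blocks, maps = {}, []
        for chrom, blk in self.blocks.items():
            off = self._offsets[chrom]
            local = keep[off : off + blk.shape[0]]
            if local.any():
                idx = np.flatnonzero(local)
                blocks[chrom] = blk[np.ix_(idx, idx)].tocsr()
                maps.append(self.snp_map.iloc[off + idx])
        if not blocks:
            raise LdError("subset removed every SNP")
        return SparseLdMatrix(
            snp_map=pd.concat(maps).reset_index(drop=True),
            blocks=blocks,
            nref=self.nref,
            chisq_threshold=self.chisq_threshold,
        )


def chisq_to_r2(threshold: float, n: float) -> float:
    """r^2 value at which ``n * r^2`` equals the chi-squared threshold."""
    if n <= 0:
        raise LdError("sample size must be positive")
    return threshold / n


@dataclass
class LdSamplingVariance:
    """Sampling variance of one LD entry under the sparsification rule."""

    s2: float
    kept: bool


def ld_sampling_variance(
    btilde: float, nref: float, ngwas: float, kept: bool
) -> LdSamplingVariance:
    """Sampling variance of a reference LD correlation.

    For a retained pair: ``s2 = (nref + ngwas) / (nref * ngwas) * (1 - btilde^2)^2``.
    For a zeroed pair the GWAS-sample LD is what remains unmodelled and
    ``s2 = 1 / ngwas``.
    """
    if nref <= 0 or ngwas <= 0:
        raise LdError("sample sizes must be positive")
    if not 0.0 <= btilde**2 <= 1.0 + 1e-12:
        raise LdError("correlation must lie in [-1, 1]")
    if kept:
        s2 = (nref + ngwas) / (nref * ngwas) * (1.0 - btilde**2) ** 2
    else:
        s2 = 1.0 / ngwas
    return LdSamplingVariance(s2=float(s2), kept=kept)


def compute_sparse_ld(
    genotypes: np.ndarray,
    snp_map: pd.DataFrame,
    chisq_threshold: float = CHISQ_DEFAULT,
) -> SparseLdMatrix:
    """Build the sparse LD matrix from a dosage matrix.

    ``genotypes`` is individuals x SNPs with dosages in {0, 1, 2} (NaN for
    missing); ``snp_map`` must have columns ``SNP chrom pos`` (``A1 A2 freq``
    are filled in if absent) in the same column order, sorted by
    (chrom, pos) within chromosome.
    """
    X = np.asarray(genotypes, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise LdError("need a 2-D dosage matrix with at least 2 individuals")
    if X.shape[1] != len(snp_map):
        raise LdError("SNP map length does not match genotype columns")
    snp_map = snp_map.copy()
    has_missing = bool(np.isnan(X).any())

    freq = np.nanmean(X, axis=0) / 2.0
    mono = (np.nanvar(X, axis=0) == 0) | (freq <= 0) | (freq >= 1)
    if mono.any():
        bad = snp_map["SNP"].iloc[int(np.flatnonzero(mono)[0])]
        raise LdError(f"monomorphic SNP {bad!r}; remove before LD computation")

    for col, val in [("A1", "A"), ("A2", "C")]:
        if col not in snp_map.columns:
            snp_map[col] = val
    if "freq" not in snp_map.columns:
        snp_map["freq"] = freq

    blocks, maps, nref_min = {}, [], np.inf
    for chrom in pd.unique(snp_map["chrom"]):
        idx = np.flatnonzero((snp_map["chrom"] == chrom).to_numpy())
        sub = X[:, idx]
        if has_missing:
            R, npair = _pairwise_complete_corr(sub)
            nref_c = npair
        else:
            Z = (sub - sub.mean(0)) / sub.std(0)
            R = (Z.T @ Z) / Z.shape[0]
            nref_c = np.full_like(R, float(Z.shape[0]))
        np.fill_diagonal(R, 1.0)
        R = np.clip(R, -1.0, 1.0)
        keep = nref_c * R**2 > chisq_threshold
        np.fill_diagonal(keep, True)
        blocks[str(chrom)] = sp.csr_matrix(np.where(keep, R, 0.0))
        maps.append(snp_map.iloc[idx])
        nref_min = min(nref_min, float(np.min(nref_c)))

    out_map = pd.concat(maps).reset_index(drop=True)
    ld = SparseLdMatrix(
        snp_map=out_map[[c for c in MAP_COLUMNS if c in out_map.columns]],
        blocks=blocks,
        nref=nref_min,
        chisq_threshold=float(chisq_threshold),
    )
    logger.info(
        "sparse LD: m=%d, mean neighbours=%.1f, threshold=%.3g",
        ld.m, float(ld.neighbour_counts().mean()), chisq_threshold,
    )
    return ld


def _pairwise_complete_corr(X: np.ndarray):
    """Pearson correlations and per-pair complete counts with missing dosages."""
    mask = ~np.isnan(X)
    Xz = np.where(mask, X, 0.0)
    n = mask.T.astype(float) @ mask.astype(float)
    s1 = Xz.T @ mask.astype(float)
    s2 = (Xz**2).T @ mask.astype(float)
    sxy = Xz.T @ Xz
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = s1 / n
        cov = sxy / n - mx * mx.T
        var = s2 / n - mx**2
        R = cov / np.sqrt(var * var.T)
    R[~np.isfinite(R)] = 0.0
    return R, n


def dense_ld(ld: SparseLdMatrix) -> np.ndarray:
    """Whole-map dense correlation matrix (block-diagonal across chromosomes)."""
    return sp.block_diag([ld.blocks[c] for c in ld.blocks], format="csr").toarray()


# ---------------------------------------------------------------------------
# binary storage

def write_ld(ld: SparseLdMatrix, path) -> None:
    """Write the sparse LD matrix in the package's binary layout."""
    header = {
        "version": FORMAT_VERSION,
        "chisq_threshold": ld.chisq_threshold,
        "nref": ld.nref,
        "chroms": [
            {"name": c, "m": int(b.shape[0]), "nnz": int(b.nnz)}
            for c, b in ld.blocks.items()
        ],
    }
    hjson = json.dumps(header).encode()
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(np.uint64(len(hjson)).tobytes())
        fh.write(hjson)
        for blk in ld.blocks.values():
            blk = blk.tocsr()
            fh.write(blk.indptr.astype(np.int64).tobytes())
            fh.write(blk.indices.astype(np.int32).tobytes())
            fh.write(blk.data.astype(np.float64).tobytes())
        buf = io.StringIO()
        ld.snp_map.to_csv(buf, sep="\t", index=False)
        fh.write(buf.getvalue().encode())


def read_ld(path) -> SparseLdMatrix:
    """Read a matrix written by :func:`write_ld`; truncation raises :class:`LdError`."""
    raw = Path(path).read_bytes()
    if raw[: len(MAGIC)] != MAGIC:
        raise LdError(f"{path}: not an LD matrix file (bad magic string)")
    off = len(MAGIC)
    (hlen,) = np.frombuffer(raw[off : off + 8], np.uint64)
    off += 8
    try:
        header = json.loads(raw[off : off + int(hlen)].decode())
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise LdError(f"{path}: corrupted header") from exc
    off += int(hlen)
    if header.get("version") != FORMAT_VERSION:
        raise LdError(f"{path}: unsupported format version {header.get('version')}")

    blocks = {}
    for spec in header["chroms"]:
        m, nnz = spec["m"], spec["nnz"]
        need = 8 * (m + 1) + 4 * nnz + 8 * nnz
        if off + need > len(raw):
            raise LdError(f"{path}: truncated file")
        indptr = np.frombuffer(raw[off : off + 8 * (m + 1)], np.int64)
        off += 8 * (m + 1)
        indices = np.frombuffer(raw[off : off + 4 * nnz], np.int32)
        off += 4 * nnz
        data = np.frombuffer(raw[off : off + 8 * nnz], np.float64)
        off += 8 * nnz
        blocks[spec["name"]] = sp.csr_matrix((data, indices, indptr), shape=(m, m))
    snp_map = pd.read_csv(io.BytesIO(raw[off:]), sep="\t", dtype={"SNP": str, "chrom": str})
    if len(snp_map) != sum(s["m"] for s in header["chroms"]):
        raise LdError(f"{path}: truncated SNP map")
    return SparseLdMatrix(
        snp_map=snp_map,
        blocks=blocks,
        nref=header["nref"],
        chisq_threshold=header["chisq_threshold"],
    )


def export_mtx(ld: SparseLdMatrix, prefix) -> None:
    """Debug export: one Matrix Market file per chromosome plus the map TSV."""
    prefix = Path(prefix)
    for chrom, blk in ld.blocks.items():
        scipy.io.mmwrite(str(prefix) + f".chr{chrom}.mtx", blk.tocoo())
    ld.snp_map.to_csv(str(prefix) + ".snpmap.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotype input

def read_dosage_text(path) -> tuple[np.ndarray, pd.DataFrame]:
    """Plain-text dosage fixture: TSV with columns SNP chrom pos A1 A2 then
    one dosage column per individual ('NA' for missing). Returns
    (individuals x SNPs matrix, SNP map)."""
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "chrom": str})
    meta = [c for c in ("SNP", "chrom", "pos", "A1", "A2") if c in df.columns]
    snp_map = df[meta].copy()
    X = df.drop(columns=meta).to_numpy(float).T
    return X, snp_map


def read_plink(prefix) -> tuple[np.ndarray, pd.DataFrame]:
    """Read a PLINK .bed/.bim/.fam triplet into dosages of the A1 allele.

    Standard 2-bit SNP-major encoding: 00 -> 2 copies of A1 is coded...
    per the PLINK spec, 00 = homozygous A1 (dosage 2 of A1), 01 = missing,
    10 = heterozygous, 11 = homozygous A2 (dosage 0). Returns
    (individuals x SNPs dosage matrix with NaN missing, SNP map).
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        pathlib_suffix(prefix, ".bim"), sep=r"\s+", header=None,
        names=["chrom", "SNP", "cm", "pos", "A1", "A2"], dtype={"chrom": str, "SNP": str},
    )
    fam = pd.read_csv(pathlib_suffix(prefix, ".fam"), sep=r"\s+", header=None)
    n, m = len(fam), len(bim)
    raw = Path(pathlib_suffix(prefix, ".bed")).read_bytes()
    if raw[:3] != b"\x6c\x1b\x01":
        raise LdError(f"{prefix}.bed: bad magic or not SNP-major")
    bpf = (n + 3) // 4  # bytes per SNP
    body = np.frombuffer(raw[3:], np.uint8)
    if body.size < m * bpf:
        raise LdError(f"{prefix}.bed: truncated")
    body = body[: m * bpf].reshape(m, bpf)
    # unpack 2-bit codes, little-endian within byte
    codes = np.empty((m, bpf * 4), np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    codes = codes[:, :n]
    lut = np.array([2.0, np.nan, 1.0, 0.0])  # code -> A1 dosage
    X = lut[codes].T
    snp_map = bim[["SNP", "chrom", "pos", "A1", "A2"]].copy()
    return X, snp_map


def write_plink(X: np.ndarray, snp_map: pd.DataFrame, prefix) -> None:
    """Write dosages to a PLINK .bed/.bim/.fam triplet (A1-dosage coding)."""
    prefix = Path(prefix)
    n, m = X.shape
    codes = np.full(X.T.shape, 1, np.uint8)  # missing
    codes[X.T == 2] = 0
    codes[X.T == 1] = 2
    codes[X.T == 0] = 3
    bpf = (n + 3) // 4
    padded = np.zeros((m, bpf * 4), np.uint8)
    padded[:, :n] = codes
    body = np.zeros((m, bpf), np.uint8)
    for k in range(4):
        body |= padded[:, k::4] << (2 * k)
    with open(pathlib_suffix(prefix, ".bed"), "wb") as fh:
        fh.write(b"\x6c\x1b\x01")
        fh.write(body.tobytes())
    bim = pd.DataFrame({
        "chrom": snp_map["chrom"], "SNP": snp_map["SNP"], "cm": 0,
        "pos": snp_map["pos"],
        "A1": snp_map.get("A1", pd.Series(["A"] * m)),
        "A2": snp_map.get("A2", pd.Series(["C"] * m)),
    })
    bim.to_csv(pathlib_suffix(prefix, ".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame({
        "fid": np.arange(1, n + 1), "iid": np.arange(1, n + 1),
        "pat": 0, "mat": 0, "sex": 0, "pheno": -9,
    })
    fam.to_csv(pathlib_suffix(prefix, ".fam"), sep="\t", header=False, index=False)
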