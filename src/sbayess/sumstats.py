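"""Reading, quality control and allele alignment of GWAS summary statistics.

The exchange format is the COJO-style ``.ma`` file: whitespace-delimited text
with a header row naming eight columns::

    SNP A1 A2 freq b se p N

where ``A1`` is the effect allele, ``freq`` the effect-allele frequency, ``b``
the marginal (per-allele) effect estimate, ``se`` its standard error, ``p``
the association p-value and ``N`` the per-SNP sample size.

A :class:`SummaryDataset` wraps these records in a :class:`pandas.DataFrame`
and carries the two scaling quantities the samplers need: the diagonal
``D_jj = 2 p_j q_j n_j`` (the genotype sum of squares under Hardy-Weinberg
equilibrium) and an estimate of the phenotypic sum of squares ``y'y``,
computed as the median of ``D_jj (n_j se_j^2 + b_j^2)`` across SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MA_COLUMNS = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]

#: Complementary-base pairs that cannot be disambiguated across strands.
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

#: Default extended MHC interval (GRCh37-style coordinates, configurable).
MHC_DEFAULT = ("6", 26_000_000, 34_000_000)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SummaryDataError(ValueError):
    """Malformed or unusable summary-statistics input."""


@dataclass
class QcReport:
    """Per-filter removal counts from :func:`qc_filter` / :func:`match_to_reference`."""

    n_input: int = 0
    n_retained: int = 0
    removed: dict = field(default_factory=dict)

    def __str__(self) -> str:  # plain-text QC log block
        lines = [f"input SNPs: {self.n_input}"]
        lines += [f"removed ({k}): {v}" for k, v in self.removed.items()]
        lines.append(f"retained SNPs: {self.n_retained}")
        return "\n".join(lines)


@dataclass
class SummaryDataset:
    """GWAS summary statistics for an ordered set of SNPs.

    ``df`` holds one row per SNP with columns ``SNP A1 A2 freq b se p N``
    (plus ``chrom``/``pos`` once matched to a reference map). ``yty`` is the
    median-based estimate of the phenotypic sum of squares; ``d`` is the
    vector of per-SNP genotype sums of squares ``D_jj``.
    """

    df: pd.DataFrame
    yty: float | None = None
    provenance: str = ""
    qc: QcReport | None = None

    def __post_init__(self) -> None:
        missing = [c for c in MA_COLUMNS if c not in self.df.columns]
        if missing:
            raise SummaryDataError(f"missing summary-statistic columns: {missing}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def d(self) -> np.ndarray:
        """Per-SNP ``D_jj = 2 p_j q_j n_j``."""
        p = self.df["freq"].to_numpy(float)
        n = self.df["N"].to_numpy(float)
        return 2.0 * p * (1.0 - p) * n

    @property
    def h(self) -> np.ndarray:
        """Per-SNP genotype variance ``h_j = 2 p_j q_j`` under HWE."""
        p = self.df["freq"].to_numpy(float)
        return 2.0 * p * (1.0 - p)

    def write_ma(self, path) -> None:
        """Round-trip the dataset back to the eight-column ``.ma`` format."""
        out = self.df[MA_COLUMNS].copy()
        out.to_csv(path, sep="\t", index=False)


def read_ma(path) -> SummaryDataset:
    """Read a COJO-style ``.ma`` summary-statistics file.

    Raises
    ------
    SummaryDataError
        If a required column is absent, a field fails to parse as a number
        (reported with its 1-based data-row index), or a row violates the
        record invariants (non-positive se, N < 2, frequency outside (0,1),
        p-value outside (0,1]).
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str, comment="#")
    missing = [c for c in MA_COLUMNS if c not in df.columns]
    if missing:
        raise SummaryDataError(
            f"{path}: missing required column(s) {missing}; header must name {MA_COLUMNS}"
        )
    df = df[MA_COLUMNS].copy()
    for col in ["freq", "b", "se", "p", "N"]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy())
        if bad.size:
            raise SummaryDataError(
                f"{path}: non-numeric value in column {col!r} at data row {bad[0] + 1}"
            )
        df[col] = vals.to_numpy(float)

    _validate_rows(df, path)
    df["A1"] = df["A1"].str.upper()
    df["A2"] = df["A2"].str.upper()
    return SummaryDataset(df=df.reset_index(drop=True), provenance=str(path))


def _validate_rows(df: pd.DataFrame, path) -> None:
    def fail(mask: np.ndarray, why: str) -> None:
        if mask.any():
            row = int(np.flatnonzero(mask)[0]) + 1
            raise SummaryDataError(f"{path}: {why} at data row {row}")

    fail((df["se"].to_numpy(float) <= 0), "non-positive standard error")
    fail((df["N"].to_numpy(float) < 2), "per-SNP sample size below 2")
    p = df["freq"].to_numpy(float)
    fail((p <= 0) | (p >= 1), "allele frequency outside (0, 1)")
    pv = df["p"].to_numpy(float)
    fail((pv <= 0) | (pv > 1), "p-value outside (0, 1]")


def qc_filter(
    ds: SummaryDataset,
    maf_min: float = 0.01,
    drop_ambiguous: bool = True,
    mhc: tuple | None = None,
) -> SummaryDataset:
    """Apply the standard summary-statistic QC filters.

    Removes SNPs with MAF below ``maf_min``, strand-ambiguous (A/T or C/G)
    allele pairs when ``drop_ambiguous``, and SNPs inside the ``mhc``
    interval ``(chrom, start, end)`` when given. MHC filtering requires
    ``chrom``/``pos`` columns (present after :func:`match_to_reference`).
    """
    if len(ds) == 0:
        raise SummaryDataError("empty dataset")
    df = ds.df
    report = QcReport(n_input=len(df))

    p = df["freq"].to_numpy(float)
    keep = np.minimum(p, 1.0 - p) >= maf_min
    report.removed["MAF below threshold"] = int((~keep).sum())

    if drop_ambiguous:
        pairs = list(zip(df["A1"], df["A2"]))
        amb = np.array([pr in AMBIGUOUS_PAIRS for pr in pairs])
        report.removed["strand-ambiguous alleles"] = int((amb & keep).sum())
        keep &= ~amb

    if mhc is not None:
        if "chrom" not in df.columns or "pos" not in df.columns:
            raise SummaryDataError(
                "MHC filtering needs chrom/pos columns; match to a reference map first"
            )
        chrom, start, end = mhc
        inside = (
            (df["chrom"].astype(str).str.lstrip("chr") == str(chrom).lstrip("chr"))
            & (df["pos"].to_numpy(float) >= start)
            & (df["pos"].to_numpy(float) <= end)
        ).to_numpy()
        report.removed["MHC region"] = int((inside & keep).sum())
        keep &= ~inside

    if not keep.any():
        raise SummaryDataError("QC removed every SNP")
    out = df.loc[keep].reset_index(drop=True)
    report.n_retained = len(out)
    logger.info("qc_filter:\n%s", report)
    return SummaryDataset(df=out, yty=None, provenance=ds.provenance, qc=report)


def match_to_reference(
    ds: SummaryDataset,
    snp_map: pd.DataFrame,
    freq_diff_max: float = 0.2,
) -> SummaryDataset:
    """Align summary statistics to a reference SNP map.

    The map must have columns ``SNP A1 A2`` (reference orientation) and
    optionally ``chrom pos freq``. SNPs absent from the map are dropped;
    where GWAS alleles are swapped relative to the reference orientation
    (directly or via strand complement) the effect is negated and the
    frequency reflected; SNPs whose alleles cannot be reconciled, or whose
    effect-allele frequency differs from the reference by more than
    ``freq_diff_max``, are dropped. Output order equals map order.
    """
    df = ds.df.set_index("SNP", drop=False)
    report = QcReport(n_input=len(ds))

    ids = [s for s in snp_map["SNP"] if s in df.index]
    report.removed["absent from reference"] = len(ds) - len(ids)
    if not ids:
        raise SummaryDataError("no SNP overlaps the reference map")

    sub = df.loc[ids].reset_index(drop=True)
    ref = snp_map.set_index("SNP").loc[ids].reset_index()

    a1, a2 = sub["A1"].to_numpy(), sub["A2"].to_numpy()
    r1, r2 = ref["A1"].astype(str).str.upper().to_numpy(), ref["A2"].astype(str).str.upper().to_numpy()
    c1 = np.array([_COMPLEMENT.get(a, "?") for a in a1])
    c2 = np.array([_COMPLEMENT.get(a, "?") for a in a2])

    same = ((a1 == r1) & (a2 == r2)) | ((c1 == r1) & (c2 == r2))
    flipped = ((a1 == r2) & (a2 == r1)) | ((c1 == r2) & (c2 == r1))
    mismatch = ~(same | flipped)
    report.removed["allele mismatch"] = int(mismatch.sum())

    b = sub["b"].to_numpy(float).copy()
    p = sub["freq"].to_numpy(float).copy()
    b[flipped] *= -1.0
    p[flipped] = 1.0 - p[flipped]
    sub["b"], sub["freq"] = b, p
    sub["A1"], sub["A2"] = r1, r2

    keep = ~mismatch
    if "freq" in ref.columns:
        discord = np.abs(p - ref["freq"].to_numpy(float)) > freq_diff_max
        report.removed["frequency discordance"] = int((discord & keep).sum())
        keep &= ~discord
    for col in ("chrom", "pos"):
        if col in ref.columns:
            sub[col] = ref[col].to_numpy()
    out = sub.loc[keep].reset_index(drop=True)
    if len(out) == 0:
        raise SummaryDataError("no SNP survived allele/frequency matching")
    report.n_retained = len(out)
    logger.info("match_to_reference:\n%s", report)
    return SummaryDataset(df=out, yty=None, provenance=ds.provenance, qc=report)


def compute_scaling(ds: SummaryDataset) -> SummaryDataset:
    """Fill in ``yty``, the median of ``D_jj (n_j se_j^2 + b_j^2)``.

    On data from a standardized phenotype this is close to n, i.e. the
    phenotypic variance times the sample size. A (near-)zero value is
    degenerate and flagged with a warning.
    """
    df = ds.df
    n = df["N"].to_numpy(float)
    se = df["se"].to_numpy(float)
    b = df["b"].to_numpy(float)
    d = ds.d
    if np.any(d <= 0):
        raise SummaryDataError("non-positive D_jj; run QC first")
    yty = float(np.median(d * (n * se**2 + b**2)))
    if yty <= 0 or not np.isfinite(yty):
        logger.warning("degenerate y'y estimate (%.3g)", yty)
    return replace(ds, yty=yty)
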