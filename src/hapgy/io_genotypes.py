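"""Genotype matrix I/O and marker/line quality filters.

Genotype calls are stored as small integers: 0 = homozygous major allele,
2 = homozygous minor allele, 1 = heterozygous, -1 = missing.  Lines are
advanced inbreds, so heterozygotes are rare; they contribute half a minor
allele to MAF computations and are treated as missing when haplotype alleles
are called downstream.

Supported formats: HapMap-style tab-delimited text, VCF v4.x (biallelic,
ploidy-2 records; multiallelic records are skipped with a logged count), and
a plain CSV call matrix (lines x markers) that round-trips through
:func:`write_matrix_csv`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING: int = -1

_IUPAC_HET = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}


class GenotypeFormatError(ValueError):
    """Raised when an input file cannot be parsed under the named format."""


class GenotypeValidationError(ValueError):
    """Raised when parsed data violates a structural invariant."""


@dataclass
class GenotypeMatrix:
    """Lines x markers call matrix with a physical marker map.

    Attributes
    ----------
    line_ids : list of str
        Unique line identifiers, one per row of ``calls``.
    marker_ids : list of str
        Unique marker identifiers, one per column of ``calls``.
    chrom : ndarray of object
        Chromosome label per marker (e.g. ``"1A"``..``"7D"`` or synthetic).
    pos_bp : ndarray of int
        1-based physical position per marker; strictly increasing within a
        chromosome after deduplication.
    calls : ndarray of int8
        Genotype codes (0 / 1 / 2 / -1 = missing).
    alleles : ndarray of object
        Per-marker ``(major, minor)`` nucleotide pair used to render
        haplotype strings; ``("A", "B")`` placeholders when unknown.
    """

    line_ids: list
    marker_ids: list
    chrom: np.ndarray
    pos_bp: np.ndarray
    calls: np.ndarray
    alleles: np.ndarray = field(default=None)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.alleles is None:
            self.alleles = np.array([("A", "B")] * len(self.marker_ids), dtype=object)
        else:
            self.alleles = np.asarray(self.alleles, dtype=object)
        self._validate()

    def _validate(self):
        n_lines, n_markers = self.calls.shape
        if n_lines != len(self.line_ids) or n_markers != len(self.marker_ids):
            raise GenotypeValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        if len(set(self.marker_ids)) != n_markers:
            dupes = pd.Index(self.marker_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise GenotypeValidationError(f"duplicated marker id(s): {dupes[:5]}")
        if len(set(self.line_ids)) != n_lines:
            raise GenotypeValidationError("duplicated line ids")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise GenotypeValidationError("calls contain codes outside {0,1,2,-1}")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def marker_missingness(self) -> np.ndarray:
        """Fraction of missing calls per marker."""
        return (self.calls == MISSING).mean(axis=0)

    def line_missingness(self) -> np.ndarray:
        """Fraction of missing calls per line."""
        return (self.calls == MISSING).mean(axis=1)

    def maf(self) -> np.ndarray:
        """Per-marker minor allele frequency from non-missing calls.

        Heterozygotes contribute one minor allele (half a dose).  Markers
        with no non-missing calls get MAF 0.
        """
        obs = self.calls != MISSING
        n_obs = obs.sum(axis=0)
        dose = np.where(obs, self.calls, 0).sum(axis=0, dtype=np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n_obs > 0, dose / (2.0 * np.maximum(n_obs, 1)), 0.0)
        return np.minimum(freq, 1.0 - freq)

    def take_markers(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            marker_ids=[self.marker_ids[i] for i in idx],
            chrom=self.chrom[idx],
            pos_bp=self.pos_bp[idx],
            calls=self.calls[:, idx],
            alleles=self.alleles[idx],
        )

    def take_lines(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            line_ids=[self.line_ids[i] for i in idx],
            calls=self.calls[idx, :],
        )

    def chromosomes(self) -> list:
        """Chromosome labels in order of first appearance."""
        seen, out = set(), []
        for c in self.chrom:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out


@dataclass
class MarkerFilterReport:
    """Bookkeeping for :func:`filter_markers`.

    ``n_input = n_output + n_removed_missing + n_removed_maf``; markers
    failing both rules are counted once, under the missingness rule.
    """

    n_input: int
    n_removed_missing: int
    n_removed_maf: int
    n_output: int
    thresholds: tuple

    def __post_init__(self):
        total = self.n_output + self.n_removed_missing + self.n_removed_maf
        if total != self.n_input:
            raise GenotypeValidationError("filter report counts inconsistent")


# ---------------------------------------------------------------------------
# readers / writers


def _dedup_and_sort(g: GenotypeMatrix) -> GenotypeMatrix:
    """Sort markers by (chromosome, position); at duplicated (chrom, pos)
    keep the marker with the lower missingness."""
    order = np.lexsort((g.pos_bp, np.asarray([str(c) for c in g.chrom])))
    g = g.take_markers(order)
    miss = g.marker_missingness()
    keep = []
    best_at = {}
    for i in range(g.n_markers):
        key = (g.chrom[i], int(g.pos_bp[i]))
        if key not in best_at:
            best_at[key] = i
            keep.append(i)
        elif miss[i] < miss[best_at[key]]:
            keep[keep.index(best_at[key])] = i
            best_at[key] = i
    if len(keep) < g.n_markers:
        logger.info("dropped %d marker(s) at duplicated positions", g.n_markers - len(keep))
    return g.take_markers(sorted(keep))


def _calls_from_nucleotides(tokens, major, minor, het_code):
    out = np.full(len(tokens), MISSING, dtype=np.int8)
    for k, t in enumerate(tokens):
        if t == major + major or t == major:
            out[k] = 0
        elif t == minor + minor or t == minor:
            out[k] = 2
        elif t in het_code:
            out[k] = 1
    return out


def _read_hapmap(path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise GenotypeFormatError(f"{path}: empty file")
        cols = header.rstrip("\n").split("\t")
        if len(cols) < 12 or cols[0] not in ("rs#", "rs"):
            raise GenotypeFormatError(f"{path}: line 1: not a HapMap header")
        line_ids = cols[11:]
        marker_ids, chroms, poss, alleles, rows = [], [], [], [], []
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            f = raw.rstrip("\n").split("\t")
            if len(f) != len(cols):
                raise GenotypeFormatError(f"{path}: line {lineno}: expected {len(cols)} fields, got {len(f)}")
            try:
                pos = int(f[3])
            except ValueError:
                raise GenotypeFormatError(f"{path}: line {lineno}: bad position {f[3]!r}") from None
            pair = f[1].replace("/", "")
            if len(pair) != 2:
                raise GenotypeFormatError(f"{path}: line {lineno}: bad allele field {f[1]!r}")
            major, minor = pair[0], pair[1]
            het = {_IUPAC_HET.get(frozenset((major, minor)), "H"), major + minor, minor + major, "AB", "BA"}
            toks = f[11:]
            calls = _calls_from_nucleotides(toks, major, minor, het)
            # accept AA/AB/BB coding too
            ab = np.array([{"AA": 0, "AB": 1, "BA": 1, "BB": 2}.get(t, MISSING) for t in toks], dtype=np.int8)
            if (calls == MISSING).sum() > (ab == MISSING).sum():
                calls = ab
            marker_ids.append(f[0])
            chroms.append(f[2])
            poss.append(pos)
            alleles.append((major, minor))
            rows.append(calls)
        if not rows:
            raise GenotypeFormatError(f"{path}: no marker records")
    calls = np.stack(rows, axis=1)
    return GenotypeMatrix(line_ids, marker_ids, chroms, poss, calls, np.array(alleles, dtype=object))


def _read_vcf(path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError:  # pragma: no cover - cyvcf2 is an optional extra
        return _read_vcf_text(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise GenotypeFormatError(f"{path}: {exc}") from exc
    line_ids = list(vcf.samples)
    marker_ids, chroms, poss, alleles, rows = [], [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = np.asarray(var.gt_types)  # 0=hom ref,1=het,2=hom alt per cyvcf2 gts012=False -> 3=unknown
        calls = np.full(len(line_ids), MISSING, dtype=np.int8)
        calls[gts == 0] = 0
        calls[gts == 1] = 1
        calls[gts == 3] = 2  # cyvcf2 default: 3 = HOM_ALT
        marker_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        alleles.append((var.REF, var.ALT[0]))
        rows.append(calls)
    if n_multi:
        logger.info("skipped %d multiallelic VCF record(s)", n_multi)
    if not rows:
        raise GenotypeFormatError(f"{path}: no biallelic records")
    calls = np.stack(rows, axis=1)
    return GenotypeMatrix(line_ids, marker_ids, chroms, poss, calls, np.array(alleles, dtype=object))


def _read_vcf_text(path) -> GenotypeMatrix:
    """Minimal text fallback for uncompressed VCF when cyvcf2 is absent."""
    line_ids = None
    marker_ids, chroms, poss, alleles, rows = [], [], [], [], []
    n_multi = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if raw.startswith("##"):
                continue
            if raw.startswith("#CHROM"):
                line_ids = raw.rstrip("\n").split("\t")[9:]
                continue
            if line_ids is None:
                raise GenotypeFormatError(f"{path}: line {lineno}: missing #CHROM header")
            f = raw.rstrip("\n").split("\t")
            if len(f) < 10:
                raise GenotypeFormatError(f"{path}: line {lineno}: too few fields")
            if "," in f[4]:
                n_multi += 1
                continue
            calls = np.full(len(line_ids), MISSING, dtype=np.int8)
            for k, cell in enumerate(f[9:]):
                gt = cell.split(":", 1)[0].replace("|", "/")
                if gt in ("0/0",):
                    calls[k] = 0
                elif gt in ("0/1", "1/0"):
                    calls[k] = 1
                elif gt == "1/1":
                    calls[k] = 2
            marker_ids.append(f[2] if f[2] != "." else f"{f[0]}_{f[1]}")
            chroms.append(f[0])
            poss.append(int(f[1]))
            alleles.append((f[3], f[4]))
            rows.append(calls)
    if n_multi:
        logger.info("skipped %d multiallelic VCF record(s)", n_multi)
    if not rows:
        raise GenotypeFormatError(f"{path}: no biallelic records")
    return GenotypeMatrix(line_ids, marker_ids, chroms, poss, np.stack(rows, axis=1), np.array(alleles, dtype=object))


def _read_matrix_csv(path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:
        raise GenotypeFormatError(f"{path}: {exc}") from exc
    if df.shape[0] < 3 or df.shape[1] == 0:
        raise GenotypeFormatError(f"{path}: matrix CSV needs 'chrom'/'pos_bp' rows plus >=1 line row")
    if list(df.index[:2]) != ["chrom", "pos_bp"]:
        raise GenotypeFormatError(f"{path}: first two rows must be 'chrom' and 'pos_bp'")
    chroms = df.iloc[0].astype(str).to_numpy(dtype=object)
    poss = df.iloc[1].astype(int).to_numpy()
    body = df.iloc[2:]
    calls = body.apply(pd.to_numeric, errors="coerce").fillna(MISSING).to_numpy(dtype=np.int8)
    return GenotypeMatrix(list(body.index), list(df.columns), chroms, poss, calls)


def read_genotypes(path, format: str = "hapmap") -> GenotypeMatrix:
    """Read a genotype matrix from ``path``.

    Parameters
    ----------
    path : str or Path
    format : {"hapmap", "vcf", "matrix-csv"}

    Returns
    -------
    GenotypeMatrix
        With markers sorted by (chromosome, position) and duplicates at the
        same position resolved in favour of the least-missing marker.
    """
    readers = {"hapmap": _read_hapmap, "vcf": _read_vcf, "matrix-csv": _read_matrix_csv}
    if format not in readers:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(readers)}")
    return _dedup_and_sort(readers[format](path))


def write_matrix_csv(g: GenotypeMatrix, path) -> None:
    """Write ``g`` in the plain CSV matrix layout that ``read_genotypes``
    with ``format='matrix-csv'`` reads back identically."""
    df = pd.DataFrame(g.calls, index=g.line_ids, columns=g.marker_ids)
    head = pd.DataFrame(
        [list(g.chrom), [int(p) for p in g.pos_bp]], index=["chrom", "pos_bp"], columns=g.marker_ids
    )
    pd.concat([head, df]).to_csv(path)


# ---------------------------------------------------------------------------
# filters


def filter_markers(
    g: GenotypeMatrix, max_missing: float = 0.30, min_maf: float = 0.15
) -> tuple:
    """Drop markers exceeding ``max_missing`` missingness or below ``min_maf``.

    Markers failing both rules are attributed to the missingness rule in the
    report.  Marker order is preserved.
    """
    if not (0 < max_missing < 1) or not (0 < min_maf < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    miss = g.marker_missingness()
    maf = g.maf()
    fail_missing = miss > max_missing
    fail_maf = (~fail_missing) & (maf < min_maf)
    keep = ~(fail_missing | fail_maf)
    report = MarkerFilterReport(
        n_input=g.n_markers,
        n_removed_missing=int(fail_missing.sum()),
        n_removed_maf=int(fail_maf.sum()),
        n_output=int(keep.sum()),
        thresholds=(max_missing, min_maf),
    )
    if report.n_output == 0:
        logger.warning("marker filter removed every marker")
    return g.take_markers(np.flatnonzero(keep)), report


def filter_lines(g: GenotypeMatrix, max_missing: float = 0.60) -> GenotypeMatrix:
    """Cull lines with more than ``max_missing`` missing calls.

    Applied after marker filtering, so line missingness is computed on the
    retained marker set.
    """
    if not (0 < max_missing < 1):
        raise ValueError("threshold must lie in (0, 1)")
    keep = g.line_missingness() <= max_missing
    if not keep.all():
        logger.info("culled %d line(s) above %.0f%% missing", (~keep).sum(), 100 * max_missing)
    return g.take_lines(np.flatnonzero(keep))
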