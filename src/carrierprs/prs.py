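"""Polygenic risk score construction.

Reads per-SNP weight tables, computes raw scores from effect-allele
dosages, standardizes them against an external reference distribution
(population controls for the breast-cancer scores, unaffected carriers
for the ovarian ones), and assigns percentile categories relative to a
reference subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("carrierprs")

VALID_ALLELES = frozenset("ACGT")

#: default column names of a tab-separated weight file (the layout used by
#: published PRS supplementary tables); override via the ``dialect`` mapping.
DEFAULT_WEIGHT_DIALECT: Mapping[str, str] = {
    "variant_id": "variant_id",
    "chromosome": "chromosome",
    "position": "position",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "weight": "weight",
    "effect_allele_frequency": "effect_allele_frequency",
}

_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class PrsFormatError(ValueError):
    """A weight or dosage file does not have the expected layout."""


class PrsValidationError(ValueError):
    """Parsed content violates a domain invariant."""


@dataclass(frozen=True)
class WeightTable:
    """Per-SNP effect alleles and log-odds-ratio weights defining one PRS."""

    table: pd.DataFrame
    name: str = ""

    def __post_init__(self) -> None:
        t = self.table
        required = ["variant_id", "chromosome", "position", "effect_allele",
                    "other_allele", "weight"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise PrsFormatError(f"weight table missing columns: {missing}")
        if len(t) == 0:
            raise PrsValidationError("weight table has no entries (empty PRS)")
        if t["variant_id"].duplicated().any():
            dups = t.loc[t["variant_id"].duplicated(), "variant_id"].tolist()
            raise PrsValidationError(f"duplicate variant ids: {dups[:5]}")
        for col in ("effect_allele", "other_allele"):
            bad = ~t[col].isin(list(VALID_ALLELES))
            if bad.any():
                raise PrsValidationError(
                    f"non-ACGT {col}: {t.loc[bad, col].unique().tolist()}")
        same = t["effect_allele"] == t["other_allele"]
        if same.any():
            raise PrsValidationError(
                f"effect allele equals other allele for "
                f"{t.loc[same, 'variant_id'].tolist()[:5]}")
        if not np.isfinite(t["weight"].to_numpy(float)).all():
            raise PrsValidationError("non-finite weights")
        if "effect_allele_frequency" in t.columns:
            f = t["effect_allele_frequency"].to_numpy(float)
            ok = np.isnan(f) | ((f > 0) & (f < 1))
            if not ok.all():
                raise PrsValidationError("allele frequencies must lie in (0,1)")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def variant_ids(self) -> list[str]:
        return self.table["variant_id"].tolist()

    @property
    def weights(self) -> np.ndarray:
        return self.table["weight"].to_numpy(float)

    @property
    def frequencies(self) -> np.ndarray:
        if "effect_allele_frequency" in self.table.columns:
            return self.table["effect_allele_frequency"].to_numpy(float)
        return np.full(len(self.table), np.nan)


@dataclass(frozen=True)
class DosageMatrix:
    """Effect-allele dosages, one row per carrier and one column per variant.

    ``counted_allele``/``other_allele`` record which allele the dosage counts
    in the source file, so scores can harmonize dosages against a weight
    table's effect allele (flipping ``g -> 2 - g`` where the file counted the
    opposite allele).
    """

    carrier_ids: list[str]
    variant_ids: list[str]
    dosages: np.ndarray  # float, NaN = missing
    counted_allele: Optional[list[str]] = None
    other_allele: Optional[list[str]] = None

    def __post_init__(self) -> None:
        d = np.asarray(self.dosages, dtype=float)
        if d.shape != (len(self.carrier_ids), len(self.variant_ids)):
            raise PrsValidationError(
                f"dosage shape {d.shape} does not match "
                f"{len(self.carrier_ids)} carriers x {len(self.variant_ids)} variants")
        with np.errstate(invalid="ignore"):
            bad = (d < 0) | (d > 2)
        if np.nansum(bad) > 0:
            raise PrsValidationError("dosages must lie in [0, 2] or be missing")
        object.__setattr__(self, "dosages", d)


@dataclass(frozen=True)
class PrsVector:
    """Raw and (optionally) standardized score per carrier."""

    carrier_ids: list[str]
    raw: np.ndarray
    standardized: Optional[np.ndarray] = None
    reference_sd: Optional[float] = None
    reference_mean: Optional[float] = None

    def to_series(self, which: str = "standardized") -> pd.Series:
        vals = getattr(self, which)
        if vals is None:
            raise PrsValidationError(f"{which} scores not populated")
        return pd.Series(vals, index=self.carrier_ids, name=f"prs_{which}")


@dataclass(frozen=True)
class PercentileScheme:
    """Percentile boundaries and the reference (baseline) category.

    The default edges reproduce the nine reporting categories
    0-5, 5-10, 10-20, 20-40, 40-60 (reference), 60-80, 80-90, 90-95, 95-100.
    """

    bin_edges: tuple[float, ...]
    thresholds: np.ndarray
    reference_bin: int

    def __post_init__(self) -> None:
        e = np.asarray(self.bin_edges, float)
        if len(e) == 0 or (e <= 0).any() or (e >= 100).any():
            raise PrsValidationError("percentile edges must lie in (0, 100)")
        if not (np.diff(e) > 0).all():
            raise PrsValidationError("percentile edges must be strictly increasing")
        if not (np.diff(self.thresholds) >= 0).all():
            raise PrsValidationError("thresholds must be nondecreasing")
        if not 0 <= self.reference_bin <= len(e):
            raise PrsValidationError("reference bin out of range")

    @property
    def n_categories(self) -> int:
        return len(self.bin_edges) + 1

    def labels(self) -> list[str]:
        edges = (0.0,) + tuple(self.bin_edges) + (100.0,)
        return [f"{edges[i]:g}-{edges[i + 1]:g}" for i in range(self.n_categories)]


DEFAULT_PERCENTILE_EDGES = (5.0, 10.0, 20.0, 40.0, 60.0, 80.0, 90.0, 95.0)
DEFAULT_REFERENCE_BIN = 4  # the 40-60 category


# ---------------------------------------------------------------------------
# weight-table and dosage IO


def read_weight_table(path, dialect: Optional[Mapping[str, str]] = None,
                      name: str = "", sep: str = "\t") -> WeightTable:
    """Read a tab-separated SNP weight file into a :class:`WeightTable`.

    ``dialect`` maps canonical field names to the file's column names; fields
    absent from the mapping fall back to :data:`DEFAULT_WEIGHT_DIALECT`.
    """
    cols = dict(DEFAULT_WEIGHT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path, sep=sep, dtype={cols["variant_id"]: str,
                                           cols["chromosome"]: str})
    required = ["variant_id", "chromosome", "position", "effect_allele",
                "other_allele", "weight"]
    for canon in required:
        if cols[canon] not in df.columns:
            raise PrsFormatError(
                f"weight file {path} lacks column {cols[canon]!r} (for {canon})")
    rename = {cols[c]: c for c in cols if cols[c] in df.columns}
    df = df.rename(columns=rename)
    keep = [c for c in DEFAULT_WEIGHT_DIALECT if c in df.columns]
    df = df[keep].copy()
    df["weight"] = pd.to_numeric(df["weight"], errors="raise")
    df["position"] = pd.to_numeric(df["position"], errors="raise").astype(int)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].str.upper()
    return WeightTable(table=df.reset_index(drop=True), name=name or str(path))


def read_dosage_tsv(path, sep: str = "\t") -> DosageMatrix:
    """Read a carriers-by-variants dosage matrix (first column = carrier id)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    return DosageMatrix(carrier_ids=[str(i) for i in df.index],
                        variant_ids=[str(c) for c in df.columns],
                        dosages=df.to_numpy(float))


def read_dosage_vcf(path, dosage_field: str = "DS") -> DosageMatrix:
    """Read dosages from a VCF with a per-genotype dosage FORMAT field.

    Falls back to hard genotype counts when the dosage field is absent for a
    record. The counted allele is ALT, as in VCF dosage convention.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, a_alt, a_ref, rows = [], [], [], []
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        try:
            ds = np.asarray(var.format(dosage_field), float).ravel()
        except (KeyError, TypeError):
            gts = np.asarray(var.gt_types)  # 0=hom_ref,1=het,2=hom_alt,3=unknown
            ds = np.where(gts == 3, np.nan,
                          np.where(gts == 2, 2.0, gts.astype(float)))
        ids.append(vid)
        a_alt.append(var.ALT[0] if var.ALT else "N")
        a_ref.append(var.REF)
        rows.append(ds)
    if not ids:
        raise PrsValidationError(f"no variant records in {path}")
    return DosageMatrix(carrier_ids=samples, variant_ids=ids,
                        dosages=np.asarray(rows).T,
                        counted_allele=a_alt, other_allele=a_ref)


# ---------------------------------------------------------------------------
# score computation


def _align_dosages(weights: WeightTable, dosages: DosageMatrix) -> np.ndarray:
    """Columns of ``dosages`` reordered to the weight table, harmonized to the
    effect allele; variants absent from the dosage matrix become all-NaN
    columns (handled downstream by the missing policy)."""
    n = len(dosages.carrier_ids)
    col_of = {v: j for j, v in enumerate(dosages.variant_ids)}
    out = np.full((n, len(weights)), np.nan)
    wt = weights.table
    for i, row in enumerate(wt.itertuples(index=False)):
        j = col_of.get(row.variant_id)
        if j is None:
            continue
        g = dosages.dosages[:, j]
        if dosages.counted_allele is not None:
            counted = dosages.counted_allele[j].upper()
            other = dosages.other_allele[j].upper() if dosages.other_allele else "N"
            if (counted, other) in _AMBIGUOUS_PAIRS:
                logger.warning(
                    "strand-ambiguous SNP %s (%s/%s): matched by allele labels only",
                    row.variant_id, counted, other)
            if counted == row.effect_allele:
                pass
            elif counted == row.other_allele and other == row.effect_allele:
                g = 2.0 - g
            elif counted == row.other_allele:
                g = 2.0 - g
            else:
                raise PrsValidationError(
                    f"alleles of {row.variant_id} ({counted}/{other}) do not match "
                    f"weight table ({row.effect_allele}/{row.other_allele})")
        out[:, i] = g
    return out


def compute_prs(weights: WeightTable, dosages: DosageMatrix,
                missing_policy: str = "impute_frequency") -> PrsVector:
    """Weighted sum of effect-allele dosages, ``raw_j = sum_i w_i g_ij``.

    missing_policy:
      ``impute_frequency`` — missing dosage replaced by ``2 f`` (its
      Hardy-Weinberg expectation); variants with missing dosage and no
      frequency raise an error;
      ``drop`` — missing dosages contribute zero for that carrier (logged);
      ``error`` — any missing dosage is an error.
    """
    if missing_policy not in ("impute_frequency", "drop", "error"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    g = _align_dosages(weights, dosages)
    w = weights.weights
    miss = np.isnan(g)
    if miss.any():
        if missing_policy == "error":
            bad = [weights.variant_ids[i] for i in np.where(miss.any(axis=0))[0]]
            raise PrsValidationError(f"missing dosages for variants: {bad[:10]}")
        freqs = weights.frequencies
        if missing_policy == "impute_frequency":
            no_freq = miss.any(axis=0) & np.isnan(freqs)
            if no_freq.any():
                bad = [weights.variant_ids[i] for i in np.where(no_freq)[0]]
                raise PrsValidationError(
                    "cannot frequency-impute variants without allele frequency: "
                    f"{bad[:10]}")
            fill = np.broadcast_to(2.0 * freqs, g.shape)
            g = np.where(miss, fill, g)
            logger.info("frequency-imputed %d missing dosages", int(miss.sum()))
        else:  # drop
            g = np.where(miss, 0.0, g)
            logger.warning("dropped %d missing dosages (contribute zero)",
                           int(miss.sum()))
    raw = g @ w
    return PrsVector(carrier_ids=list(dosages.carrier_ids), raw=raw)


def standardize_prs(prs: PrsVector, reference_sd: float,
                    reference_mean: float = 0.0) -> PrsVector:
    """Express the score in per-SD units of an external reference distribution."""
    if not np.isfinite(reference_sd) or reference_sd <= 0:
        raise PrsValidationError(f"reference SD must be positive, got {reference_sd}")
    std = (prs.raw - reference_mean) / reference_sd
    return replace(prs, standardized=std, reference_sd=float(reference_sd),
                   reference_mean=float(reference_mean))


def assign_percentiles(prs: PrsVector, reference_ids: Sequence[str],
                       scheme_edges: Sequence[float] = DEFAULT_PERCENTILE_EDGES,
                       reference_bin: int = DEFAULT_REFERENCE_BIN,
                       which: str = "standardized",
                       ) -> tuple[PercentileScheme, np.ndarray]:
    """Label every carrier with the percentile category of their score.

    Thresholds are type-7 (linear-interpolation) empirical quantiles of the
    ``reference_ids`` subset (in the study, unaffected carriers); categories
    are half-open ``[lower, upper)`` so ties fall to the lower bin.
    Returns the scheme plus an integer category per carrier.
    """
    vals = prs.to_series(which)
    ref = vals.loc[[str(i) for i in reference_ids]].to_numpy(float)
    if len(ref) == 0:
        raise PrsValidationError("reference set is empty")
    edges = np.asarray(scheme_edges, float)
    if len(ref) < len(edges) + 1:
        raise PrsValidationError(
            f"reference set of {len(ref)} is smaller than the "
            f"{len(edges) + 1} categories")
    if np.ptp(ref) == 0:
        raise PrsValidationError("all reference scores identical: quantiles degenerate")
    thresholds = np.quantile(ref, edges / 100.0)  # type-7 default
    scheme = PercentileScheme(bin_edges=tuple(edges), thresholds=thresholds,
                              reference_bin=reference_bin)
    labels = np.searchsorted(thresholds, vals.to_numpy(float), side="right")
    return scheme, labels
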