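"""Somatic-mutation landscape: MAF parsing, substitution spectra,
per-gene burden and carrier co-occurrence.

Coordinates follow the MAF convention: 1-based inclusive, insertions
anchored at the base before the inserted sequence (ref written ``-``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import FormatError, ValidationError

log = logging.getLogger(__name__)

VARIANT_CLASSES = (
    "missense",
    "nonsense",
    "silent",
    "splice_site",
    "frame_shift_ins",
    "frame_shift_del",
    "in_frame_ins",
    "in_frame_del",
    "translation_start_site",
    "other",
)

#: default mapping from canonical field -> MAF column header
DEFAULT_COLUMN_MAP = {
    "sample_id": "Tumor_Sample_Barcode",
    "gene": "Hugo_Symbol",
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
    "variant_class": "Variant_Classification",
    "transcript_biotype": "Transcript_Biotype",
}

#: common MAF Variant_Classification spellings -> closed vocabulary
_CLASS_ALIASES = {
    "missense_mutation": "missense",
    "nonsense_mutation": "nonsense",
    "silent": "silent",
    "splice_site": "splice_site",
    "frame_shift_ins": "frame_shift_ins",
    "frame_shift_del": "frame_shift_del",
    "in_frame_ins": "in_frame_ins",
    "in_frame_del": "in_frame_del",
    "translation_start_site": "translation_start_site",
}


@dataclass(frozen=True)
class MutationRecord:
    """One somatic call."""

    sample_id: str
    gene: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    variant_class: str = "other"
    transcript_biotype: str = "other"

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(
                f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}"
            )
        if self.variant_class not in VARIANT_CLASSES:
            raise ValidationError(f"unknown variant class {self.variant_class!r}")

    @property
    def mutation_id(self) -> str:
        return f"{self.sample_id}:{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and "-" not in (self.ref, self.alt)


def _normalize_class(raw: str) -> str:
    key = str(raw).strip().lower()
    if key in VARIANT_CLASSES:
        return key
    if key in _CLASS_ALIASES:
        return _CLASS_ALIASES[key]
    log.warning("unknown variant class %r mapped to 'other'", raw)
    return "other"


def read_maf(path: str | Path, column_map: dict[str, str] | None = None) -> list[MutationRecord]:
    """Parse a MAF-like TSV into validated :class:`MutationRecord` objects.

    ``column_map`` maps canonical field names to the file's header names;
    unspecified fields fall back to the standard MAF headers.
    """
    cmap = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    required = ["sample_id", "gene", "chrom", "pos", "ref", "alt"]
    for fieldname in required:
        if cmap[fieldname] not in df.columns:
            raise FormatError(f"missing required column {cmap[fieldname]!r} in {path}")
    has_class = cmap["variant_class"] in df.columns
    has_biotype = cmap["transcript_biotype"] in df.columns
    records = []
    for row in df.itertuples(index=False, name=None):
        vals = dict(zip(df.columns, row))
        records.append(
            MutationRecord(
                sample_id=str(vals[cmap["sample_id"]]),
                gene=str(vals[cmap["gene"]]),
                chrom=str(vals[cmap["chrom"]]),
                pos=int(vals[cmap["pos"]]),
                ref=str(vals[cmap["ref"]]),
                alt=str(vals[cmap["alt"]]),
                variant_class=_normalize_class(vals[cmap["variant_class"]]) if has_class else "other",
                transcript_biotype=str(vals[cmap["transcript_biotype"]]) if has_biotype else "other",
            )
        )
    return records


def write_maf(records: Iterable[MutationRecord], path: str | Path) -> None:
    rows = [
        {
            DEFAULT_COLUMN_MAP["sample_id"]: r.sample_id,
            DEFAULT_COLUMN_MAP["gene"]: r.gene,
            DEFAULT_COLUMN_MAP["chrom"]: r.chrom,
            DEFAULT_COLUMN_MAP["pos"]: r.pos,
            DEFAULT_COLUMN_MAP["ref"]: r.ref,
            DEFAULT_COLUMN_MAP["alt"]: r.alt,
            DEFAULT_COLUMN_MAP["variant_class"]: r.variant_class,
            DEFAULT_COLUMN_MAP["transcript_biotype"]: r.transcript_biotype,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(DEFAULT_COLUMN_MAP.values())).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------- spectra

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_PYRIMIDINES = {"C", "T"}
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def classify_substitution(ref: str, alt: str) -> tuple[str, str] | None:
    """Classify a single-base substitution into its pyrimidine-normalized
    six-class form and transition/transversion status.

    Purine reference alleles are complemented so every class starts from
    C or T. Returns ``None`` for non-single-nucleotide alleles, which are
    excluded from Ti/Tv tallies.
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        return None
    if ref == alt:
        raise ValidationError("ref == alt is not a substitution")
    titv = "transition" if (ref, alt) in _TRANSITIONS else "transversion"
    if ref not in _PYRIMIDINES:
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}", titv


def substitution_spectrum(records: Iterable[MutationRecord]) -> pd.DataFrame:
    """Counts and fractions of the six substitution classes and Ti/Tv."""
    classes = []
    for r in records:
        c = classify_substitution(r.ref, r.alt) if r.is_snv() else None
        if c is not None:
            classes.append(c)
    df = pd.DataFrame(classes, columns=["class6", "titv"])
    if df.empty:
        return pd.DataFrame(columns=["class6", "titv", "count", "fraction"])
    out = df.value_counts().rename("count").reset_index()
    out["fraction"] = out["count"] / out["count"].sum()
    return out.sort_values("class6").reset_index(drop=True)


def summarize_by_gene(records: Sequence[MutationRecord]) -> pd.DataFrame:
    """Per-gene mutation count, carrier-sample count and class breakdown.

    Class fractions per gene sum to 1; carriers count unique samples.
    """
    if not records:
        return pd.DataFrame(
            columns=["gene", "n_mutations", "n_carriers", *VARIANT_CLASSES]
        )
    df = pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "sample_id": [r.sample_id for r in records],
            "variant_class": [r.variant_class for r in records],
        }
    )
    counts = df.groupby("gene").agg(
        n_mutations=("sample_id", "size"), n_carriers=("sample_id", "nunique")
    )
    frac = (
        df.groupby(["gene", "variant_class"]).size().unstack(fill_value=0)
        .reindex(columns=VARIANT_CLASSES, fill_value=0)
    )
    frac = frac.div(frac.sum(axis=1), axis=0)
    out = counts.join(frac).reset_index()
    return out.sort_values(["n_mutations", "gene"], ascending=[False, True]).reset_index(
        drop=True
    )


def per_sample_burden(records: Iterable[MutationRecord]) -> pd.Series:
    """Total mutation count per sample."""
    s = pd.Series([r.sample_id for r in records], dtype=str)
    return s.value_counts().sort_index()


# ---------------------------------------------------------------- matrix


@dataclass
class MutationMatrix:
    """Gene x sample mutation-count matrix with boolean carrier masks.

    Multiple mutations of one gene in one sample count fully in ``counts``
    but once in ``carrier_mask``.
    """

    counts: pd.DataFrame  # genes x samples, int
    carrier_mask: pd.DataFrame = field(init=False)

    def __post_init__(self):
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValidationError("duplicate gene or sample labels")
        if not np.isfinite(self.counts.values).all() or (self.counts.values < 0).any():
            raise ValidationError("counts must be finite non-negative integers")
        self.carrier_mask = self.counts > 0

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


def build_mutation_matrix(
    records: Sequence[MutationRecord],
    samples: Sequence[str],
    min_carrier_samples: int = 2,
    *,
    on_unknown_sample: str = "skip",
) -> MutationMatrix:
    """Build the gene x sample count matrix, keeping genes mutated in at
    least ``min_carrier_samples`` samples.

    ``samples`` is the full sample universe, so samples without any
    mutation appear as zero columns; records from samples outside the
    universe are skipped with a warning (or raise with
    ``on_unknown_sample='error'``). Idempotent: re-filtering a filtered
    matrix changes nothing.
    """
    samples = list(samples)
    universe = set(samples)
    rows: dict[tuple[str, str], int] = {}
    for r in records:
        if r.sample_id not in universe:
            if on_unknown_sample == "error":
                raise ValidationError(f"sample {r.sample_id!r} not in universe")
            log.warning("skipping record from unknown sample %s", r.sample_id)
            continue
        rows[(r.gene, r.sample_id)] = rows.get((r.gene, r.sample_id), 0) + 1
    genes = sorted({g for g, _ in rows})
    counts = pd.DataFrame(0, index=genes, columns=samples, dtype=int)
    for (g, s), n in rows.items():
        counts.at[g, s] = n
    keep = (counts > 0).sum(axis=1) >= min_carrier_samples
    return MutationMatrix(counts.loc[keep])


def pairwise_cooccurrence(
    matrix: MutationMatrix, genes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Fisher's exact test of carrier co-occurrence for every gene pair.

    Returns a long-format table with odds ratio (``inf`` sentinel for
    perfect co-occurrence), two-sided exact p, Benjamini-Hochberg adjusted
    p and a direction label (co-occurrence when OR > 1, exclusivity
    otherwise).
    """
    if genes is None:
        genes = matrix.genes
    genes = list(genes)
    missing = [g for g in genes if g not in matrix.counts.index]
    if missing:
        raise ValidationError(f"genes absent from matrix: {missing}")
    if len(genes) < 2:
        raise ValidationError("need at least 2 genes")
    mask = matrix.carrier_mask.loc[genes].values
    rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            a = int(np.sum(mask[i] & mask[j]))
            b = int(np.sum(mask[i] & ~mask[j]))
            c = int(np.sum(~mask[i] & mask[j]))
            d = int(np.sum(~mask[i] & ~mask[j]))
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append(
                {
                    "gene_a": genes[i],
                    "gene_b": genes[j],
                    "n_both": a,
                    "n_a_only": b,
                    "n_b_only": c,
                    "n_neither": d,
                    "odds_ratio": odds,
                    "p_value": p,
                    "direction": "co-occurrence" if odds > 1 else "exclusivity",
                }
            )
    out = pd.DataFrame(rows)
    out["p_adj"] = stats.false_discovery_control(out["p_value"], method="bh")
    return out
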