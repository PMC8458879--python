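"""MRE disruption by lncRNA somatic mutations and the resulting
mutation-miRNA-lncRNA (ceRNA) regulation units.

The stage relocates each lncRNA mutation into transcript coordinates,
extracts a 21-nt-upstream / 7-nt-downstream window around the site in
both wild and mutant form, scores miRNA binding with two independent
scorers — a miRanda-style seed-weighted local alignment with a
nearest-neighbor duplex-energy surrogate, and a TargetScan-style
seed-site context score — and classifies the wild-to-mutant change of
the best reliable site into gain / up / loss / down.

Reliability thresholds follow the analysis protocol: alignment score
> 160 with duplex energy < -20 kcal/mol, or context score < -0.4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    AlphabetError,
    InestimableError,
    MissingSequenceError,
    ReferenceMismatchError,
    ValidationError,
)
from .landscape import MutationRecord

log = logging.getLogger(__name__)

RNA_BASES = "ACGU"
_RNA_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}
_DNA_TO_RNA = str.maketrans("Tt", "Uu")
_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def rna_complement(base: str) -> str:
    return _RNA_COMPLEMENT[base]


def rna_revcomp(seq: str) -> str:
    return "".join(_RNA_COMPLEMENT[b] for b in reversed(seq))


def _check_rna(seq: str, what: str) -> str:
    seq = seq.upper().translate(_DNA_TO_RNA)
    bad = set(seq) - set(RNA_BASES)
    if bad:
        raise AlphabetError(f"{what} contains non-RNA characters {sorted(bad)}")
    return seq


# ------------------------------------------------------------ transcripts


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure of one transcript (1-based inclusive genomic intervals)."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "other"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: no exons")
        prev_end = 0
        for s, e in self.exons:
            if s > e or s < 1:
                raise ValidationError(f"{self.transcript_id}: bad exon ({s},{e})")
            if s <= prev_end:
                raise ValidationError(f"{self.transcript_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def contains(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)


def transcripts_from_exon_table(exons: pd.DataFrame) -> dict[str, TranscriptModel]:
    """Group an exon table (as from :func:`cernamut.io.read_gtf_exons`)."""
    models = {}
    for tid, grp in exons.groupby("transcript_id", sort=True):
        grp = grp.sort_values("start")
        models[tid] = TranscriptModel(
            transcript_id=str(tid),
            gene_id=str(grp["gene_id"].iloc[0]),
            chrom=str(grp["chrom"].iloc[0]),
            strand=str(grp["strand"].iloc[0]),
            exons=tuple((int(s), int(e)) for s, e in zip(grp["start"], grp["end"])),
            biotype=str(grp["biotype"].iloc[0]),
        )
    return models


def transcripts_to_exon_table(models: Iterable[TranscriptModel]) -> pd.DataFrame:
    rows = []
    for t in models:
        for s, e in t.exons:
            rows.append(
                {
                    "transcript_id": t.transcript_id,
                    "gene_id": t.gene_id,
                    "chrom": t.chrom,
                    "strand": t.strand,
                    "start": s,
                    "end": e,
                    "biotype": t.biotype,
                }
            )
    return pd.DataFrame(rows)


def map_genomic_to_transcript(pos: int, transcript: TranscriptModel) -> int | None:
    """Genomic position -> 1-based transcript coordinate, or None if not exonic.

    Strand-aware: on the minus strand position 1 is the 3'-most genomic
    base of the last exon.
    """
    offset = 0
    if transcript.strand == "+":
        for s, e in transcript.exons:
            if s <= pos <= e:
                return offset + (pos - s + 1)
            offset += e - s + 1
    else:
        for s, e in reversed(transcript.exons):
            if s <= pos <= e:
                return offset + (e - pos + 1)
            offset += e - s + 1
    return None


def map_transcript_to_genomic(t_pos: int, transcript: TranscriptModel) -> int:
    """Inverse of :func:`map_genomic_to_transcript` for exonic positions."""
    if not 1 <= t_pos <= transcript.spliced_length:
        raise ValidationError(f"t_pos {t_pos} outside transcript")
    remaining = t_pos
    exons = transcript.exons if transcript.strand == "+" else tuple(reversed(transcript.exons))
    for s, e in exons:
        length = e - s + 1
        if remaining <= length:
            return s + remaining - 1 if transcript.strand == "+" else e - remaining + 1
        remaining -= length
    raise AssertionError("unreachable")


# ------------------------------------------------------------ windows


@dataclass(frozen=True)
class SequenceWindowPair:
    """Wild and mutant MRE windows around one lncRNA mutation."""

    mutation: MutationRecord | None
    lncrna: str
    t_pos: int
    wild_seq: str
    mut_seq: str
    up_len: int
    down_len: int


def extract_window(
    transcript_seq: str,
    t_pos: int,
    ref: str,
    alt: str,
    *,
    up: int = 21,
    down: int = 7,
    mutation: MutationRecord | None = None,
    lncrna: str = "",
) -> SequenceWindowPair:
    """Extract the wild/mutant window pair around a transcript mutation.

    ``ref``/``alt`` are in transcript orientation (RNA alphabet; ``-`` or
    empty strings denote insertion/deletion sides). Flanks are truncated
    at transcript ends; for insertions the anchor base at ``t_pos``
    precedes the inserted bases.
    """
    seq = _check_rna(transcript_seq, "transcript sequence")
    ref = "" if ref == "-" else _check_rna(ref, "ref") if ref else ""
    alt = "" if alt == "-" else _check_rna(alt, "alt") if alt else ""
    if ref == alt:
        raise ValidationError("ref == alt")
    if not 1 <= t_pos <= len(seq):
        raise ValidationError(f"t_pos {t_pos} outside transcript of length {len(seq)}")
    anchor_len = len(ref) if ref else 1  # insertions anchor on the base at t_pos
    if t_pos - 1 + anchor_len > len(seq):
        raise ReferenceMismatchError(f"ref allele runs past transcript end at t_pos {t_pos}")
    if ref and seq[t_pos - 1 : t_pos - 1 + len(ref)] != ref:
        raise ReferenceMismatchError(
            f"transcript has {seq[t_pos - 1 : t_pos - 1 + len(ref)]!r} at t_pos {t_pos}, "
            f"expected {ref!r}"
        )
    up_len = min(up, t_pos - 1)
    down_len = min(down, len(seq) - (t_pos - 1 + anchor_len))
    start = t_pos - 1 - up_len
    end = t_pos - 1 + anchor_len + down_len
    wild = seq[start:end]
    if ref:
        mut = wild[:up_len] + alt + wild[up_len + len(ref) :]
    else:  # insertion: inserted bases between the anchor and the downstream flank
        mut = wild[: up_len + 1] + alt + wild[up_len + 1 :]
    return SequenceWindowPair(
        mutation=mutation,
        lncrna=lncrna,
        t_pos=t_pos,
        wild_seq=wild,
        mut_seq=mut,
        up_len=up_len,
        down_len=down_len,
    )


# ------------------------------------------------------------ alignment scorer


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters of the seed-weighted local aligner."""

    match: float = 5.0
    wobble: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -2.0
    seed_start: int = 2  # miRNA positions scaled
    seed_end: int = 8
    seed_scale: float = 4.0
    score_floor: float = 10.0  # candidate sites below this are dropped
    terminal_au_penalty: float = 0.45


def _load_stack_table() -> dict[str, float]:
    with resources.files("cernamut.data").joinpath("rna_stack_energies.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    return dict(zip(df["step"], df["delta_g"]))


_STACK_DG = _load_stack_table()


@dataclass(frozen=True)
class AlignmentSite:
    """One candidate duplex between a window and a miRNA."""

    align_score: float
    duplex_energy: float
    site_start: int  # 1-based window coords of the aligned target region
    site_end: int
    pairs: tuple[tuple[int, int], ...] = ()  # (window pos, miRNA pos), 1-based


def _pair_score(a: str, b: str, mirna_pos: int, p: AlignmentParams) -> float:
    if (a, b) in _WC:
        s = p.match
    elif (a, b) in _WOBBLE:
        s = p.wobble
    else:
        s = p.mismatch
    if p.seed_start <= mirna_pos <= p.seed_end:
        s *= p.seed_scale
    return s


def duplex_energy(window: str, pairs: Sequence[tuple[int, int]], mirna: str,
                  p: AlignmentParams = AlignmentParams()) -> float:
    """Nearest-neighbor free-energy surrogate of an aligned duplex.

    Sums bundled Watson-Crick stacking terms over consecutive paired
    positions; gaps, mismatches and wobble-containing stacks contribute
    0; each end of a maximal Watson-Crick run closing on an A-U pair
    pays a +0.45 terminal penalty.
    """
    wc = [
        (wi, mi)
        for wi, mi in pairs
        if (window[wi - 1], mirna[mi - 1]) in _WC
    ]
    energy = 0.0
    run: list[tuple[int, int]] = []

    def close_run():
        nonlocal energy
        if not run:
            return
        for (w1, _), (w2, _) in zip(run, run[1:]):
            energy += _STACK_DG[window[w1 - 1] + window[w2 - 1]]
        for idx in (0, -1):
            wi, mi = run[idx]
            if {window[wi - 1], mirna[mi - 1]} == {"A", "U"}:
                energy += p.terminal_au_penalty
        run.clear()

    for wi, mi in wc:
        if run and (wi - run[-1][0] != 1 or run[-1][1] - mi != 1):
            close_run()
        run.append((wi, mi))
    close_run()
    return energy


def _smith_waterman(window: str, q: str, m: int, p: AlignmentParams, masked: set[int]):
    """Affine-gap local DP of the reversed miRNA ``q`` against ``window``.

    ``masked`` holds 0-based window indices excluded from alignment.
    Returns (best score, aligned (window_pos, mirna_pos) pairs, 1-based
    window start/end) or None if nothing scores positive.
    """
    n = len(window)
    NEG = -1e9
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), NEG)  # gap in miRNA (window base bulged)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in window (miRNA base bulged)
    # traceback pointers: state preceding each cell ("", start of alignment)
    PM = np.empty((n + 1, m + 1), dtype=object)
    PIx = np.empty((n + 1, m + 1), dtype=object)
    PIy = np.empty((n + 1, m + 1), dtype=object)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if (i - 1) in masked:
                PM[i, j] = ""
                continue
            mirna_pos = m - (j - 1)
            s = _pair_score(window[i - 1], q[j - 1], mirna_pos, p)
            prev_best, prev_state = 0.0, ""
            for val, name in (
                (M[i - 1, j - 1], "M"),
                (Ix[i - 1, j - 1], "Ix"),
                (Iy[i - 1, j - 1], "Iy"),
            ):
                if val > prev_best:
                    prev_best, prev_state = val, name
            M[i, j] = max(0.0, prev_best + s)
            PM[i, j] = prev_state if M[i, j] > 0 else ""
            if M[i - 1, j] + p.gap_open >= Ix[i - 1, j] + p.gap_extend:
                Ix[i, j], PIx[i, j] = M[i - 1, j] + p.gap_open, "M"
            else:
                Ix[i, j], PIx[i, j] = Ix[i - 1, j] + p.gap_extend, "Ix"
            if M[i, j - 1] + p.gap_open >= Iy[i, j - 1] + p.gap_extend:
                Iy[i, j], PIy[i, j] = M[i, j - 1] + p.gap_open, "M"
            else:
                Iy[i, j], PIy[i, j] = Iy[i, j - 1] + p.gap_extend, "Iy"
    best = float(M.max())
    if best <= 0:
        return None
    i, j = np.unravel_index(int(M.argmax()), M.shape)
    pairs = []
    state = "M"
    si, sj = int(i), int(j)
    while si > 0 and sj > 0 and state:
        if state == "M":
            pairs.append((si, m - (sj - 1)))
            state = PM[si, sj]
            si, sj = si - 1, sj - 1
        elif state == "Ix":
            state = PIx[si, sj]
            si -= 1
        else:
            state = PIy[si, sj]
            sj -= 1
    pairs.reverse()
    return best, tuple(pairs), pairs[0][0], pairs[-1][0]


def scan_alignment_scorer(
    window: str,
    mirna: str,
    params: AlignmentParams = AlignmentParams(),
    *,
    max_sites: int = 3,
) -> list[AlignmentSite]:
    """Score candidate miRNA binding sites in a window.

    Complementarity is scored by local dynamic programming of the
    reversed miRNA against the window (Watson-Crick +5, G:U wobble +2,
    mismatch -3, affine gaps -8/-2) with pair contributions at miRNA seed
    positions 2-8 scaled by 4. Each site carries a nearest-neighbor
    duplex-energy surrogate. Non-overlapping suboptimal sites above the
    score floor are returned best-first; thresholding is the caller's
    concern.
    """
    window = _check_rna(window, "window")
    mirna = _check_rna(mirna, "miRNA")
    if len(window) < 6:
        raise ValidationError("window must be at least 6 nt")
    if not 18 <= len(mirna) <= 26:
        raise ValidationError("miRNA length must be 18-26 nt")
    q = mirna[::-1]
    m = len(mirna)
    masked: set[int] = set()
    sites: list[AlignmentSite] = []
    for _ in range(max_sites):
        hit = _smith_waterman(window, q, m, params, masked)
        if hit is None:
            break
        score, pairs, w_start, w_end = hit
        if score < params.score_floor:
            break
        sites.append(
            AlignmentSite(
                align_score=score,
                duplex_energy=duplex_energy(window, pairs, mirna, params),
                site_start=w_start,
                site_end=w_end,
                pairs=pairs,
            )
        )
        masked.update(range(w_start - 1, w_end))
    return sites


# ------------------------------------------------------------ context scorer


@dataclass(frozen=True)
class ContextParams:
    """Site-type and context terms of the seed-site scorer."""

    site_scores: Mapping[str, float] = field(
        default_factory=lambda: {
            "8mer": -0.35,
            "7mer-m8": -0.20,
            "7mer-A1": -0.12,
            "6mer": -0.05,
        }
    )
    three_prime_per_pair: float = -0.01
    three_prime_floor: float = -0.05
    three_prime_start: int = 13  # miRNA positions contributing 3' pairing
    three_prime_end: int = 17
    local_au_weight: float = -0.10


@dataclass(frozen=True)
class ContextSite:
    context_score: float
    site_type: str
    site_start: int  # 1-based window coords
    site_end: int


def context_scorer(
    window: str, mirna: str, params: ContextParams = ContextParams()
) -> ContextSite | None:
    """Detect the best canonical seed site and score its context.

    Seed sites require exact Watson-Crick complementarity to miRNA
    positions 2-7; the m8 pair and a target A opposite position 1 extend
    the type to 7mer-m8 / 7mer-A1 / 8mer. The context score adds the
    site-type term, a 3'-supplementary term (-0.01 per consecutive pair
    over miRNA 13-17, floored at -0.05) and a local-AU term (-0.10 times
    the AU fraction of the window outside the seed). More negative is
    stronger; returns None when no seed match exists.
    """
    window = _check_rna(window, "window")
    mirna = _check_rna(mirna, "miRNA")
    if len(mirna) < 8:
        raise ValidationError("miRNA too short for seed analysis")
    seed6 = rna_revcomp(mirna[1:7])  # pairs miRNA positions 2-7
    best: ContextSite | None = None
    for i in range(len(window) - 5):
        if window[i : i + 6] != seed6:
            continue
        has_m8 = i - 1 >= 0 and (window[i - 1], mirna[7]) in _WC
        has_t1a = i + 6 < len(window) and window[i + 6] == "A"
        if has_m8 and has_t1a:
            site_type = "8mer"
        elif has_m8:
            site_type = "7mer-m8"
        elif has_t1a:
            site_type = "7mer-A1"
        else:
            site_type = "6mer"
        start = i - 1 if has_m8 else i
        end = i + 6 if has_t1a else i + 5
        # 3'-supplementary pairing: longest consecutive WC run over 13-17
        t1_idx = i + 6  # window index opposite miRNA position 1
        run = best_run = 0
        for p3 in range(params.three_prime_start, params.three_prime_end + 1):
            t_idx = t1_idx - (p3 - 1)
            if (
                p3 <= len(mirna)
                and 0 <= t_idx < len(window)
                and (window[t_idx], mirna[p3 - 1]) in _WC
            ):
                run += 1
                best_run = max(best_run, run)
            else:
                run = 0
        three_prime = max(
            params.three_prime_floor, params.three_prime_per_pair * best_run
        )
        outside = window[:start] + window[end + 1 :]
        au_frac = (
            sum(1 for b in outside if b in "AU") / len(outside) if outside else 0.0
        )
        score = (
            params.site_scores[site_type]
            + three_prime
            + params.local_au_weight * au_frac
        )
        cand = ContextSite(score, site_type, start + 1, end + 1)
        if best is None or cand.context_score < best.context_score:
            best = cand
    return best


# ------------------------------------------------------------ calls & states


@dataclass(frozen=True)
class Thresholds:
    """Reliability thresholds for miRNA site calls."""

    min_align_score: float = 160.0
    max_energy: float = -20.0
    max_context: float = -0.4
    mode: str = "union"  # or "intersection"


@dataclass(frozen=True)
class MirnaSiteCall:
    """Merged verdict of both scorers for one window/miRNA pair."""

    mirna_id: str
    site_start: int
    site_end: int
    site_type: str  # 8mer/7mer-m8/7mer-A1/6mer/none
    align_score: float
    duplex_energy: float
    context_score: float | None
    passed_by: frozenset[str]

    @property
    def reliable(self) -> bool:
        return bool(self.passed_by)


def call_sites(
    window: str,
    mirna: str,
    mirna_id: str = "",
    thresholds: Thresholds = Thresholds(),
    align_params: AlignmentParams = AlignmentParams(),
    context_params: ContextParams = ContextParams(),
) -> list[MirnaSiteCall]:
    """Run both scorers on a window and merge their calls.

    The context site (if any) is merged into the overlapping alignment
    site; ``passed_by`` records which scorer(s) the call satisfies under
    the thresholds. In ``intersection`` mode both are required for a
    call to count as reliable.
    """
    aln_sites = scan_alignment_scorer(window, mirna, align_params)
    ctx = context_scorer(window, mirna, context_params)
    calls = []
    ctx_used = False
    for site in aln_sites:
        overlaps = ctx is not None and not (
            ctx.site_end < site.site_start or ctx.site_start > site.site_end
        )
        c_score = ctx.context_score if overlaps else None
        s_type = ctx.site_type if overlaps else "none"
        if overlaps:
            ctx_used = True
        passed = set()
        if site.align_score > thresholds.min_align_score and site.duplex_energy < thresholds.max_energy:
            passed.add("alignment_scorer")
        if c_score is not None and c_score < thresholds.max_context:
            passed.add("context_scorer")
        if thresholds.mode == "intersection" and len(passed) < 2:
            passed = set()
        calls.append(
            MirnaSiteCall(
                mirna_id, site.site_start, site.site_end, s_type,
                site.align_score, site.duplex_energy, c_score, frozenset(passed),
            )
        )
    if ctx is not None and not ctx_used:
        passed = set()
        if ctx.context_score < thresholds.max_context:
            passed.add("context_scorer")
        if thresholds.mode == "intersection":
            passed = set()
        calls.append(
            MirnaSiteCall(
                mirna_id, ctx.site_start, ctx.site_end, ctx.site_type,
                0.0, 0.0, ctx.context_score, frozenset(passed),
            )
        )
    return calls


def best_call(calls: Iterable[MirnaSiteCall]) -> MirnaSiteCall | None:
    """Best reliable call: max alignment score, ties by lower duplex
    energy, then leftmost site."""
    reliable = [c for c in calls if c.reliable]
    if not reliable:
        return None
    return min(reliable, key=lambda c: (-c.align_score, c.duplex_energy, c.site_start))


STATES = ("gain", "up", "loss", "down")


def classify_affinity_change(
    wild_calls: Iterable[MirnaSiteCall],
    mut_calls: Iterable[MirnaSiteCall],
    tol: float = 1e-9,
) -> str:
    """Classify the wild-to-mutant change of the best reliable site.

    gain: mutant-only; loss: wild-only; up/down: both present with the
    mutant alignment score strictly higher/lower; anything else is
    ``unchanged`` (and produces no regulation unit).
    """
    wb = best_call(wild_calls)
    mb = best_call(mut_calls)
    if wb is None and mb is None:
        return "unchanged"
    if wb is None:
        return "gain"
    if mb is None:
        return "loss"
    delta = mb.align_score - wb.align_score
    if delta > tol:
        return "up"
    if delta < -tol:
        return "down"
    return "unchanged"


@dataclass(frozen=True)
class RegulationUnit:
    """One mutation-miRNA-lncRNA unit with its affinity-change state."""

    mutation_id: str
    mirna_id: str
    lncrna_id: str
    state: str
    wild_best: MirnaSiteCall | None
    mut_best: MirnaSiteCall | None

    def __post_init__(self):
        if self.state not in STATES:
            raise ValidationError(f"state must be one of {STATES}")
        if self.state == "gain" and (self.wild_best is not None or self.mut_best is None):
            raise ValidationError("gain requires a mutant-only site")
        if self.state == "loss" and (self.mut_best is not None or self.wild_best is None):
            raise ValidationError("loss requires a wild-only site")
        if self.state in ("up", "down") and (self.wild_best is None or self.mut_best is None):
            raise ValidationError(f"{self.state} requires sites on both sequences")


def build_units(
    mutations: Sequence[MutationRecord],
    transcripts: Mapping[str, TranscriptModel] | Sequence[TranscriptModel],
    lncrna_seqs: Mapping[str, str],
    mirna_seqs: Mapping[str, str],
    thresholds: Thresholds = Thresholds(),
    *,
    up: int = 21,
    down: int = 7,
    align_params: AlignmentParams = AlignmentParams(),
    context_params: ContextParams = ContextParams(),
) -> list[RegulationUnit]:
    """Assemble regulation units for every exonic lncRNA mutation.

    Each mutation is relocated onto every overlapping lncRNA transcript;
    wild and mutant windows are scored against every miRNA, and one unit
    is emitted per non-unchanged pair, ordered by (mutation, miRNA).
    """
    if not isinstance(transcripts, Mapping):
        transcripts = {t.transcript_id: t for t in transcripts}
    lnc_tx = [t for t in transcripts.values() if t.biotype == "lncRNA"]
    units: list[RegulationUnit] = []
    for mut in mutations:
        for tx in lnc_tx:
            if tx.chrom != mut.chrom:
                continue
            t_pos = map_genomic_to_transcript(mut.pos, tx)
            if t_pos is None:
                continue
            try:
                seq = lncrna_seqs[tx.transcript_id]
            except KeyError:
                raise MissingSequenceError(
                    f"no sequence for transcript {tx.transcript_id}"
                ) from None
            ref = "" if mut.ref == "-" else mut.ref
            alt = "" if mut.alt == "-" else mut.alt
            if tx.strand == "-":
                ref_t, alt_t = rna_revcomp(ref.translate(_DNA_TO_RNA).upper()), rna_revcomp(
                    alt.translate(_DNA_TO_RNA).upper()
                )
                if ref:
                    t_pos = map_genomic_to_transcript(mut.pos + len(ref) - 1, tx) or t_pos
            else:
                ref_t, alt_t = ref, alt
            try:
                pair = extract_window(
                    seq, t_pos, ref_t, alt_t, up=up, down=down,
                    mutation=mut, lncrna=tx.transcript_id,
                )
            except ReferenceMismatchError as exc:
                log.warning("skipping %s on %s: %s", mut.mutation_id, tx.transcript_id, exc)
                continue
            for mirna_id in sorted(mirna_seqs):
                wild_calls = call_sites(
                    pair.wild_seq, mirna_seqs[mirna_id], mirna_id,
                    thresholds, align_params, context_params,
                )
                mut_calls = call_sites(
                    pair.mut_seq, mirna_seqs[mirna_id], mirna_id,
                    thresholds, align_params, context_params,
                )
                state = classify_affinity_change(wild_calls, mut_calls)
                if state == "unchanged":
                    continue
                wb, mb = best_call(wild_calls), best_call(mut_calls)
                units.append(
                    RegulationUnit(
                        mutation_id=mut.mutation_id,
                        mirna_id=mirna_id,
                        lncrna_id=tx.transcript_id,
                        state=state,
                        wild_best=wb if state in ("loss", "up", "down") else None,
                        mut_best=mb if state in ("gain", "up", "down") else None,
                    )
                )
    units.sort(key=lambda u: (u.mutation_id, u.mirna_id, u.lncrna_id))
    return units


def units_to_frame(units: Sequence[RegulationUnit]) -> pd.DataFrame:
    rows = []
    for u in units:
        rows.append(
            {
                "mutation_id": u.mutation_id,
                "mirna_id": u.mirna_id,
                "lncrna_id": u.lncrna_id,
                "state": u.state,
                "wild_score": u.wild_best.align_score if u.wild_best else np.nan,
                "mut_score": u.mut_best.align_score if u.mut_best else np.nan,
                "wild_energy": u.wild_best.duplex_energy if u.wild_best else np.nan,
                "mut_energy": u.mut_best.duplex_energy if u.mut_best else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mutation_id", "mirna_id", "lncrna_id", "state",
            "wild_score", "mut_score", "wild_energy", "mut_energy",
        ],
    )


def extend_to_mrna(
    units: Sequence[RegulationUnit], validated_targets: pd.DataFrame
) -> tuple[pd.DataFrame, nx.Graph]:
    """Join units with a validated miRNA->mRNA target table into the
    mutation-lncRNA-miRNA-mRNA dysregulation network.

    Returns a typed edge table and the corresponding graph; node degree
    ranking comes from the graph. miRNAs absent from the table simply
    gain no mRNA edges.
    """
    edges = []
    graph = nx.Graph()
    for u in units:
        for a, b, kind in (
            (f"mut:{u.mutation_id}", f"lnc:{u.lncrna_id}", "mutation-lncRNA"),
            (f"lnc:{u.lncrna_id}", f"mir:{u.mirna_id}", "lncRNA-miRNA"),
        ):
            if not graph.has_edge(a, b):
                graph.add_edge(a, b, kind=kind)
                edges.append({"source": a, "target": b, "kind": kind, "state": u.state})
    if not validated_targets.empty:
        unit_mirnas = {u.mirna_id for u in units}
        for row in validated_targets.itertuples(index=False):
            if row.mirna_id in unit_mirnas:
                a, b = f"mir:{row.mirna_id}", f"mrna:{row.mrna_gene}"
                if not graph.has_edge(a, b):
                    graph.add_edge(a, b, kind="miRNA-mRNA")
                    edges.append(
                        {"source": a, "target": b, "kind": "miRNA-mRNA", "state": ""}
                    )
    edge_df = pd.DataFrame(edges, columns=["source", "target", "kind", "state"])
    return edge_df, graph


def one_sample_expression_test(mut_value: float, wt_values: np.ndarray) -> tuple[float, float]:
    """One-sample t-test of the wild-type expression distribution against
    a single mutant sample's value as the hypothesized mean."""
    wt = np.asarray(wt_values, dtype=float)
    if len(wt) < 3:
        raise InestimableError("need >= 3 wild-type values")
    if np.std(wt) == 0:
        raise InestimableError("zero variance in wild-type values")
    t, p = stats.ttest_1samp(wt, popmean=float(mut_value))
    return float(t), float(p)
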