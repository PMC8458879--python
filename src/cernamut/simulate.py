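"""Synthetic cohort generator with planted ground truth for every
pipeline stage.

The generator emulates a pancreatic-tumor style cohort: a MAF of somatic
calls with a handful of expression-driver genes (carriers shifted by a
configurable log2 fold change), lncRNAs carrying mutations engineered to
create / strengthen / destroy / weaken seed-complementary miRNA sites,
and survival times driven by a linear predictor over chosen genes with
independent uniform censoring. Everything is deterministic under a fixed
seed, and the planted truth tables enumerate every effect so downstream
stages can be scored against them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as cio
from .cerna import (
    AlignmentParams,
    ContextParams,
    Thresholds,
    TranscriptModel,
    call_sites,
    classify_affinity_change,
    extract_window,
    map_transcript_to_genomic,
    rna_complement,
    transcripts_to_exon_table,
)
from .exceptions import ConfigError, ValidationError
from .landscape import MutationRecord, write_maf

log = logging.getLogger(__name__)

_RNA_TO_DNA = str.maketrans("Uu", "Tt")
_DNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

STATES = ("gain", "up", "loss", "down")
DEFAULT_MODES = ("gain", "up", "loss", "down") * 3


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic cohort.

    Defaults approximate the real analysis setting at desk scale: ~180
    samples, drivers shifted by a 4-fold (log2 FC = 2) expression change
    in ~30% of samples, three planted regulation units per state, an
    exponential survival model with a median around one year and ~30%
    censoring.
    """

    n_samples: int = 180
    n_genes: int = 300
    n_lncrnas: int = 12
    n_mirnas: int = 10
    n_drivers: int = 8
    driver_log2fc: float = 2.0
    carrier_rate: float = 0.3
    passenger_rate: float = 3.0  # Poisson mean passenger mutations per sample
    mre_modes: tuple[str, ...] = DEFAULT_MODES
    risk_coefficients: Mapping[str, float] | None = None
    baseline_hazard: float = 1.0 / 500.0  # per day
    censoring_rate: float = 0.3
    lncrna_length: int = 400
    seed: int = 0

    def __post_init__(self):
        for name in ("n_samples", "n_genes", "n_lncrnas", "n_mirnas", "n_drivers"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.n_drivers > self.n_genes:
            raise ConfigError("n_drivers must not exceed n_genes")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ConfigError("censoring_rate must lie in [0, 1]")
        if not 0.0 < self.carrier_rate <= 1.0:
            raise ConfigError("carrier_rate must lie in (0, 1]")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be positive")
        if any(m not in STATES for m in self.mre_modes):
            raise ConfigError(f"mre_modes must be drawn from {STATES}")
        if self.mre_modes and self.n_lncrnas < len(self.mre_modes):
            raise ConfigError("need at least one lncRNA per planted unit")
        if self.lncrna_length < 40:
            raise ConfigError("lncrna_length must be >= 40")


@dataclass(frozen=True)
class PlantedEdit:
    """Transcript-space description of one planted MRE mutation."""

    t_pos: int
    ref: str  # transcript-orientation RNA alleles
    alt: str
    mode: str


@dataclass
class SyntheticCohort:
    """All inputs of a pipeline run plus the planted truth tables."""

    config: SimConfig
    mutations: list[MutationRecord]
    expression: pd.DataFrame  # genes x samples
    clinical: pd.DataFrame  # index sample: os_days, event, stage
    transcripts: dict[str, TranscriptModel]
    lncrna_fasta: dict[str, str]
    mirna_fasta: dict[str, str]
    genome_fasta: dict[str, str]
    mirna_targets: pd.DataFrame
    truth: dict[str, pd.DataFrame] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Serialize every input as plain text; returns {name: path}."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        def emit(name, fn):
            p = outdir / name
            fn(p)
            paths[name.split(".")[0]] = str(p)

        emit("mutations.maf.tsv", lambda p: write_maf(self.mutations, p))
        emit("expression.tsv", lambda p: cio.write_expression(self.expression, p))
        emit(
            "clinical.tsv",
            lambda p: self.clinical.to_csv(p, sep="\t", index_label="sample_id",
                                           float_format="%.6g"),
        )
        emit(
            "annotation.gtf",
            lambda p: cio.write_gtf_exons(
                transcripts_to_exon_table(
                    [self.transcripts[k] for k in sorted(self.transcripts)]
                ),
                p,
            ),
        )
        emit("lncrna.fa", lambda p: cio.write_fasta(self.lncrna_fasta, p))
        emit("mirna.fa", lambda p: cio.write_fasta(self.mirna_fasta, p))
        emit("genome.fa", lambda p: cio.write_fasta(self.genome_fasta, p))
        emit("mirna_targets.tsv", lambda p: cio.write_tsv(self.mirna_targets, p))
        for name, df in sorted(self.truth.items()):
            emit(f"truth_{name}.tsv", lambda p, df=df: cio.write_tsv(df, p))
        return paths


# ------------------------------------------------------------ MRE planting


def _random_rna(rng: np.random.Generator, length: int, au_bias: float = 0.0) -> str:
    p_au = 0.25 + au_bias / 2
    p_gc = 0.25 - au_bias / 2
    return "".join(
        rng.choice(list("AUGC"), p=[p_au, p_au, p_gc, p_gc]) for _ in range(length)
    )


def _site_window(
    mirna: str, k: int, anchor_pos: int, broken: bool, flanks: str, *, up: int = 21, down: int = 7
) -> str:
    """Build a window whose indices [a+p-k, a+p-1] (a = anchor index, p =
    anchored miRNA position) hold the complement of miRNA positions 1..k,
    with a target A opposite position 1 and, when ``broken``, the anchor
    base replaced by the miRNA base itself (neither Watson-Crick nor
    wobble)."""
    a = up  # 0-based anchor index in the window
    window = list(flanks[: up + 1 + down])
    for q in range(1, k + 1):
        idx = a + anchor_pos - q
        if not 0 <= idx < len(window):
            raise ValidationError("site does not fit the window")
        window[idx] = rna_complement(mirna[q - 1])
    if anchor_pos != 1:
        # target adenine opposite miRNA position 1 (t1-A rule) so the
        # context scorer can see an 8mer when the seed is intact
        window[a + anchor_pos - 1] = "A"
    if broken:
        window[a] = mirna[anchor_pos - 1]
    return "".join(window)


def plant_mre_mutation(
    lncrna_seq: str,
    mirna_seq: str,
    mode: str,
    *,
    t_pos: int | None = None,
    rng: np.random.Generator | None = None,
    thresholds: Thresholds = Thresholds(),
    align_params: AlignmentParams = AlignmentParams(),
    context_params: ContextParams = ContextParams(),
) -> tuple[str, PlantedEdit]:
    """Engineer a single-base MRE mutation of the requested mode.

    The returned wild lncRNA sequence and edit are guaranteed (verified
    with the actual scorers) to classify as ``mode``: for ``gain`` the
    wild window hosts no reliable site and the mutant does (the planted
    site is complementary to miRNA positions 1..k with the seed broken
    opposite miRNA position 4 in the wild sequence); ``loss`` is the
    mirror; ``up``/``down`` keep a reliable site on both sequences and
    repair/introduce a mismatch opposite miRNA position 1, strictly
    raising/lowering the best alignment score.
    """
    if mode not in STATES:
        raise ConfigError(f"mode must be one of {STATES}")
    seq = cio.normalize_rna(lncrna_seq)
    mirna = cio.normalize_rna(mirna_seq)
    if len(seq) < 40:
        raise ValidationError("lncRNA too short to host a window (need >= 40 nt)")
    up, down = 21, 7
    if t_pos is None:
        t_pos = max(up + 1, min(len(seq) - down, len(seq) // 2))
    if t_pos - 1 < up or len(seq) - t_pos < down:
        raise ValidationError("t_pos too close to the transcript end for full flanks")
    rng = rng or np.random.default_rng(0)
    flanks = _random_rna(rng, up + 1 + down, au_bias=0.3)

    seed_break = mode in ("gain", "loss")
    anchor_pos = 4 if seed_break else 1
    k_candidates = (17, 16, 15, 14, 13, 12) if seed_break else (len(mirna), len(mirna) - 1)
    for k in k_candidates:
        if k > len(mirna):
            continue
        strong = _site_window(mirna, k, anchor_pos, broken=False, flanks=flanks)
        weak = _site_window(mirna, k, anchor_pos, broken=True, flanks=flanks)
        if mode in ("gain", "up"):
            wild_window, mut_window = weak, strong
        else:
            wild_window, mut_window = strong, weak
        ref, alt = wild_window[up], mut_window[up]
        if ref == alt:
            continue
        calls = lambda w: call_sites(w, mirna, "m", thresholds, align_params, context_params)
        if classify_affinity_change(calls(wild_window), calls(mut_window)) != mode:
            continue
        wild_seq = seq[: t_pos - 1 - up] + wild_window + seq[t_pos + down :]
        # closed-loop check through the real extraction path
        pair = extract_window(wild_seq, t_pos, ref, alt, up=up, down=down)
        if classify_affinity_change(calls(pair.wild_seq), calls(pair.mut_seq)) == mode:
            return wild_seq, PlantedEdit(t_pos=t_pos, ref=ref, alt=alt, mode=mode)
    raise ValidationError(
        f"could not plant a {mode} site for this miRNA (no k satisfied the scorers)"
    )


# ------------------------------------------------------------ survival


def simulate_survival(
    expression: pd.DataFrame,
    coefficients: Mapping[str, float],
    baseline_hazard: float,
    censoring_rate: float,
    seed: int,
) -> pd.DataFrame:
    """Exponential survival times with hazard h0 * exp(linear predictor).

    The linear predictor runs over log2(x+1) expression, matching the
    scale of the survival models. Censoring is independent uniform on
    [0, c], with c calibrated by bisection so the realised censoring
    fraction approximates the request. Returns a frame indexed by sample
    with positive ``os_days`` and binary ``event``.
    """
    if not 0.0 <= censoring_rate <= 1.0:
        raise ConfigError("censoring_rate must lie in [0, 1]")
    missing = [g for g in coefficients if g not in expression.index]
    if missing:
        raise ValidationError(f"coefficient genes absent from expression: {missing}")
    rng = np.random.default_rng(seed)
    samples = list(expression.columns)
    lp = np.zeros(len(samples))
    for gene, coef in coefficients.items():
        lp += coef * np.log2(expression.loc[gene].values.astype(float) + 1.0)
    rate = baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    if censoring_rate == 0 or len(samples) == 0:
        os_days, event = t_event, np.ones(len(samples), dtype=int)
    else:

        def realised(c):
            return float(np.mean(np.minimum(t_event / c, 1.0)))

        lo, hi = 1e-6, float(t_event.max()) * 1e3 + 1.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if realised(mid) > censoring_rate:
                lo = mid
            else:
                hi = mid
        c_max = 0.5 * (lo + hi)
        c = rng.uniform(0.0, c_max, size=len(samples))
        event = (t_event <= c).astype(int)
        os_days = np.minimum(t_event, c)
    return pd.DataFrame(
        {"os_days": np.maximum(os_days, 1e-6), "event": event},
        index=pd.Index(samples, name="sample_id"),
    )


# ------------------------------------------------------------ cohort


def _dna(seq: str) -> str:
    return seq.translate(_RNA_TO_DNA).upper()


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort described by ``config``.

    Deterministic under a fixed seed; with ``n_samples=0`` everything,
    including the truth tables, is empty.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"S{i + 1:04d}" for i in range(n)]
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]

    # --- expression: log-normal noise around gene baselines -------------
    baselines = rng.lognormal(mean=3.0, sigma=1.0, size=config.n_genes)
    noise = rng.lognormal(mean=0.0, sigma=0.35, size=(config.n_genes, n))
    expr = baselines[:, None] * noise
    expression = pd.DataFrame(expr, index=genes, columns=samples)

    mutations: list[MutationRecord] = []
    truth_driver_rows = []
    driver_genes = genes[: config.n_drivers] if n else []
    gene_chrom = {g: "chr1" for g in genes}
    gene_span = {g: (i * 2000 + 1, i * 2000 + 1500) for i, g in enumerate(genes)}

    if n:
        for g in driver_genes:
            n_carriers = max(2, int(rng.binomial(n, config.carrier_rate)))
            n_carriers = min(n_carriers, n)
            carriers = sorted(rng.choice(n, size=n_carriers, replace=False))
            expression.loc[g, [samples[i] for i in carriers]] *= 2.0**config.driver_log2fc
            lo, hi = gene_span[g]
            for i in carriers:
                pos = int(rng.integers(lo, hi + 1))
                ref = str(rng.choice(list("ACGT")))
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                mutations.append(
                    MutationRecord(
                        sample_id=samples[i], gene=g, chrom=gene_chrom[g], pos=pos,
                        ref=ref, alt=alt, variant_class="missense",
                        transcript_biotype="protein_coding",
                    )
                )
            truth_driver_rows.append(
                {"gene": g, "log2fc": config.driver_log2fc, "n_carriers": n_carriers}
            )

        # passengers: Poisson count per sample over non-driver genes
        passenger_pool = genes[config.n_drivers :] or genes
        classes = ["missense", "nonsense", "silent", "splice_site"]
        for i, s in enumerate(samples):
            for _ in range(int(rng.poisson(config.passenger_rate))):
                g = passenger_pool[int(rng.integers(len(passenger_pool)))]
                lo, hi = gene_span[g]
                pos = int(rng.integers(lo, hi + 1))
                ref = str(rng.choice(list("ACGT")))
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                mutations.append(
                    MutationRecord(
                        sample_id=s, gene=g, chrom=gene_chrom[g], pos=pos, ref=ref,
                        alt=alt, variant_class=str(rng.choice(classes)),
                        transcript_biotype="protein_coding",
                    )
                )

    # --- protein-coding annotation (single exon, + strand) --------------
    transcripts: dict[str, TranscriptModel] = {}
    for g in genes:
        lo, hi = gene_span[g]
        transcripts[f"{g}-T1"] = TranscriptModel(
            transcript_id=f"{g}-T1", gene_id=g, chrom=gene_chrom[g], strand="+",
            exons=((lo, hi),), biotype="protein_coding",
        )

    # --- miRNAs ---------------------------------------------------------
    mirna_ids = [f"miR-{i + 1:03d}" for i in range(config.n_mirnas)]
    mirna_fasta = {m: _random_rna(rng, 22) for m in mirna_ids}

    # --- lncRNAs with planted MRE mutations -----------------------------
    lncrna_fasta: dict[str, str] = {}
    genome_fasta: dict[str, str] = {}
    truth_unit_rows = []
    L = config.lncrna_length
    plant_modes = list(config.mre_modes) if (n and config.n_mirnas) else []
    for u in range(config.n_lncrnas):
        gene_id = f"LNC{u + 1:02d}"
        tid = f"{gene_id}-T1"
        chrom = f"chrL{u + 1:02d}"
        multi_exon = u == config.n_lncrnas - 1  # minus-strand, multi-exon fixture
        if multi_exon:
            e1, e2, e3 = (1001, 1150), (1351, 1500), (1701, 1700 + (L - 300))
            tx = TranscriptModel(tid, gene_id, chrom, "-", (e1, e2, e3), "lncRNA")
        else:
            tx = TranscriptModel(tid, gene_id, chrom, "+", ((1001, 1000 + L),), "lncRNA")
        transcripts[tid] = tx
        background = _random_rna(rng, L)
        if u < len(plant_modes):
            mode = plant_modes[u]
            mirna_id = mirna_ids[u % config.n_mirnas]
            wild_seq, edit = plant_mre_mutation(
                background, mirna_fasta[mirna_id], mode, rng=rng
            )
            sample_id = samples[int(rng.integers(n))]
            g_pos = map_transcript_to_genomic(edit.t_pos, tx)
            if tx.strand == "+":
                ref_g, alt_g = _dna(edit.ref), _dna(edit.alt)
            else:
                ref_g = _DNA_COMPLEMENT[_dna(edit.ref)]
                alt_g = _DNA_COMPLEMENT[_dna(edit.alt)]
            rec = MutationRecord(
                sample_id=sample_id, gene=gene_id, chrom=chrom, pos=g_pos,
                ref=ref_g, alt=alt_g, variant_class="other", transcript_biotype="lncRNA",
            )
            mutations.append(rec)
            truth_unit_rows.append(
                {
                    "mutation_id": rec.mutation_id,
                    "lncrna_id": tid,
                    "mirna_id": mirna_id,
                    "mode": mode,
                    "t_pos": edit.t_pos,
                }
            )
        else:
            wild_seq = background
        lncrna_fasta[tid] = wild_seq
        # genome: random chromosome with the transcript written through the
        # exon map (complemented on the minus strand)
        span_end = tx.exons[-1][1] + 200
        chrom_seq = list(_dna(_random_rna(rng, span_end)))
        for t in range(1, tx.spliced_length + 1):
            gpos = map_transcript_to_genomic(t, tx)
            base = _dna(wild_seq[t - 1])
            chrom_seq[gpos - 1] = base if tx.strand == "+" else _DNA_COMPLEMENT[base]
        genome_fasta[chrom] = "".join(chrom_seq)

    # --- survival -------------------------------------------------------
    coeffs = config.risk_coefficients
    if coeffs is None:
        coeffs = (
            {genes[-1]: 1.0, genes[-2]: -1.0} if config.n_genes >= 2 and n else {}
        )
    if n:
        clinical = simulate_survival(
            expression, coeffs, config.baseline_hazard, config.censoring_rate,
            seed=int(rng.integers(2**31 - 1)),
        )
        clinical["stage"] = rng.choice(["I", "II", "III", "IV"], size=n)
    else:
        clinical = pd.DataFrame(columns=["os_days", "event", "stage"],
                                index=pd.Index([], name="sample_id"))

    # --- validated miRNA -> mRNA target table ---------------------------
    target_rows = []
    if n and config.n_genes:
        for m in mirna_ids:
            for g in rng.choice(genes, size=min(3, config.n_genes), replace=False):
                target_rows.append({"mirna_id": m, "mrna_gene": g, "evidence": "synthetic"})
    mirna_targets = pd.DataFrame(target_rows, columns=["mirna_id", "mrna_gene", "evidence"])

    mutations.sort(key=lambda r: (r.sample_id, r.chrom, r.pos, r.ref, r.alt))
    truth = {
        "drivers": pd.DataFrame(truth_driver_rows, columns=["gene", "log2fc", "n_carriers"]),
        "units": pd.DataFrame(
            truth_unit_rows, columns=["mutation_id", "lncrna_id", "mirna_id", "mode", "t_pos"]
        ),
        "risk": pd.DataFrame(
            sorted(coeffs.items()) if n else [], columns=["gene", "coefficient"]
        ),
    }
    return SyntheticCohort(
        config=config,
        mutations=mutations,
        expression=expression,
        clinical=clinical,
        transcripts=transcripts,
        lncrna_fasta=lncrna_fasta,
        mirna_fasta=mirna_fasta,
        genome_fasta=genome_fasta,
        mirna_targets=mirna_targets,
        truth=truth,
    )
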