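"""Synthetic inputs for every pipeline stage, with controllable ground truth.

Each generator emulates one class of input the analysis consumes — dose
matrices with embedded additivity excesses, differential cistromes skewed
into enhancer chromatin states, treatment-skewed DEG tables, NES tables
with direction-switching terms, a two-subtype tumor cohort, and region
sequences with planted motifs — so every downstream stage can be tested
against a known truth without any external data.

Determinism contract: the same :class:`SimulationConfig` (same seed)
produces byte-identical outputs. Each generator draws from its own
seed stream (``default_rng([seed, stream])``) so adding one generator
call never perturbs another's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval, RegionSet
from .motifs import PWM
from .screen import PlateMeasurements
from .signature import CohortMatrix

#: default chromatin-state vocabulary and genome-wide frequencies
CHROMHMM_STATES = {
    "Promoter": 0.08,
    "Bivalent_Promoter": 0.04,
    "Active_Enhancer": 0.12,
    "Poised_Enhancer": 0.12,
    "Polycomb": 0.08,
    "Quiescent": 0.56,
}
ENHANCER_STATES = ("Active_Enhancer", "Poised_Enhancer")

GENE_CLASS_PROBS = {
    "CoA": 0.05,
    "CoR": 0.05,
    "Mixed": 0.05,
    "TF": 0.10,
    "NR": 0.03,
    "other": 0.72,
}

# per-generator seed streams
_STREAMS = {
    "plate": 1,
    "cistromes": 2,
    "genes": 3,
    "deg": 4,
    "nes": 5,
    "cohort": 6,
    "sequences": 7,
    "collection": 8,
}


@dataclass
class SimulationConfig:
    """Shared knobs for all generators.

    plate_noise_sd is in percent-viability units; embedded_delta_map maps
    a (doseA, doseB) pair to the percent-inhibition excess planted there;
    loss_enhancer_enrichment is the odds multiplier with which loss sites
    prefer enhancer chromatin states; switch_fraction is the proportion of
    NES terms planted with opposite sign between conditions.
    """

    seed: int = 0
    genome: tuple[tuple[str, int], ...] = (("chr1", 10_000_000), ("chr2", 10_000_000))
    n_genes: int = 2000
    n_tumors: int = 100
    plate_noise_sd: float = 5.0
    embedded_delta_map: dict[tuple[float, float], float] = field(default_factory=dict)
    deg_fraction: float = 0.2
    lfc_sd: float = 0.4
    loss_enhancer_enrichment: float = 10.0
    switch_fraction: float = 0.1

    def __post_init__(self) -> None:
        for name, length in self.genome:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        for name, value in (
            ("deg_fraction", self.deg_fraction),
            ("switch_fraction", self.switch_fraction),
        ):
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.plate_noise_sd < 0:
            raise ValueError("plate_noise_sd must be >= 0")
        if self.loss_enhancer_enrichment < 1:
            raise ValueError(
                "loss_enhancer_enrichment < 1 contradicts the requested "
                "loss-into-enhancer skew; use 1 for no skew"
            )

    @property
    def genome_map(self) -> dict[str, int]:
        return dict(self.genome)

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


# ---------------------------------------------------------------------------
# Combination-screen plates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HillParams:
    """4-parameter Hill inhibition curve: 0 at dose 0, rising to ``top``."""

    top: float = 90.0
    bottom: float = 0.0
    ec50: float = 1.0
    slope: float = 1.5

    def inhibition(self, dose: float) -> float:
        if dose <= 0:
            return self.bottom
        return self.bottom + (self.top - self.bottom) / (
            1.0 + (self.ec50 / dose) ** self.slope
        )


def simulate_screen_plate(
    config: SimulationConfig,
    doses_a: list[float],
    doses_b: list[float],
    n_replicates: int = 4,
    hill_a: HillParams = HillParams(ec50=0.5),
    hill_b: HillParams = HillParams(ec50=1.0),
    control_level: float = 1_000_000.0,
    n_control_wells: int = 16,
) -> PlateMeasurements:
    """Simulate a dose-matrix viability plate with control wells.

    Both dose lists must be strictly increasing and include the zero
    dose. Combination inhibition is the capped (at 100) sum of the two
    Hill monotherapy inhibitions, plus any planted excess from
    ``config.embedded_delta_map``, plus Gaussian noise on percent
    viability truncated to [0, 120]. Raw light units scale viability by
    ``control_level``.
    """
    for doses, tag in ((doses_a, "A"), (doses_b, "B")):
        if len(doses) < 1 or any(
            d2 <= d1 for d1, d2 in zip(doses, doses[1:])
        ):
            raise ValueError(f"drug {tag} dose list must be strictly increasing")
        if doses[0] != 0:
            raise ValueError(f"drug {tag} dose list must include the zero dose")
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates")
    rng = config.rng("plate")
    rows = []
    for da in doses_a:
        for db in doses_b:
            inh = min(hill_a.inhibition(da) + hill_b.inhibition(db), 100.0)
            inh += config.embedded_delta_map.get((da, db), 0.0)
            for rep in range(1, n_replicates + 1):
                viability = 100.0 - inh + rng.normal(0.0, config.plate_noise_sd)
                viability = float(np.clip(viability, 0.0, 120.0))
                rows.append(
                    {
                        "drugA_dose": da,
                        "drugB_dose": db,
                        "replicate": rep,
                        "raw": viability / 100.0 * control_level,
                        "is_control": False,
                    }
                )
    for i in range(n_control_wells):
        viability = float(
            np.clip(100.0 + rng.normal(0.0, config.plate_noise_sd), 0.0, 120.0)
        )
        rows.append(
            {
                "drugA_dose": 0.0,
                "drugB_dose": 0.0,
                "replicate": i + 1,
                "raw": viability / 100.0 * control_level,
                "is_control": True,
            }
        )
    return PlateMeasurements(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Differential cistromes + chromatin-state segmentation
# ---------------------------------------------------------------------------

def simulate_chromhmm(
    config: SimulationConfig,
    states: dict[str, float] | None = None,
    segment_length: int = 2000,
    rng: np.random.Generator | None = None,
) -> RegionSet:
    """Tile the genome into fixed-width segments with random state labels."""
    states = states or CHROMHMM_STATES
    rng = rng if rng is not None else config.rng("cistromes")
    names = list(states)
    probs = np.array([states[s] for s in names], dtype=float)
    probs = probs / probs.sum()
    intervals = []
    for chrom, length in config.genome:
        n_seg = length // segment_length
        labels = rng.choice(len(names), size=n_seg, p=probs)
        for i in range(n_seg):
            start = i * segment_length
            intervals.append(
                GenomicInterval(
                    chrom, start, start + segment_length, 0.0, "none", names[labels[i]]
                )
            )
    return RegionSet("chromhmm", intervals, config.genome_map)


def simulate_differential_cistromes(
    config: SimulationConfig,
    factors: list[str],
    n_loss: int = 500,
    n_gain: int = 300,
    shared_block: int = 50,
    site_width: int = 400,
    states: dict[str, float] | None = None,
    segment_length: int = 2000,
) -> tuple[dict[str, RegionSet], RegionSet]:
    """Per-factor differential-binding sets plus a ChromHMM segmentation.

    Each site occupies one segmentation segment: loss sites sit in the
    left half of their segment and gain sites in the right half, so the
    two directions of one factor never overlap even when they choose the
    same segment; within a direction segments are drawn without
    replacement. Loss sites choose their segment with odds multiplied by
    ``config.loss_enhancer_enrichment`` for the poised-enhancer state and
    by a third of that excess for active enhancers (loss of binding
    concentrates most strongly in poised enhancers); gain sites choose
    uniformly. The first ``shared_block`` loss sites of the first two
    factors share identical coordinates, planting a known overlap between
    them. Scores are lognormal.
    """
    if not factors:
        raise ValueError("factors must be non-empty")
    if segment_length < 2 * site_width:
        raise ValueError("segment_length must be >= 2 * site_width")
    rng = config.rng("cistromes")
    segmentation = simulate_chromhmm(config, states, segment_length, rng)
    segs = segmentation.intervals
    n_segs = len(segs)
    m = config.loss_enhancer_enrichment
    state_odds = {"Poised_Enhancer": m, "Active_Enhancer": 1.0 + (m - 1.0) / 3.0}
    loss_w = np.array([state_odds.get(iv.name, 1.0) for iv in segs])
    loss_w = loss_w / loss_w.sum()
    half = segment_length // 2

    def place(seg_idx: np.ndarray, direction: str, factor: str, tag: str,
              coords: list | None = None) -> list[GenomicInterval]:
        lo = 0 if direction == "loss" else half
        hi = (half if direction == "loss" else segment_length) - site_width
        out = []
        for j, si in enumerate(seg_idx):
            seg = segs[si]
            if coords is not None:
                chrom, start = coords[j]
            else:
                offset = int(rng.integers(lo, hi + 1))
                chrom, start = seg.chrom, seg.start + offset
            score = float(rng.lognormal(1.5, 0.5))
            out.append(
                GenomicInterval(
                    chrom, start, start + site_width, score, direction,
                    f"{factor}_{tag}_{j}",
                )
            )
        return out

    shared_block = min(shared_block, n_loss) if len(factors) >= 2 else 0
    shared_idx = rng.choice(n_segs, size=shared_block, replace=False, p=loss_w)
    shared_coords = []
    for si in shared_idx:
        seg = segs[si]
        offset = int(rng.integers(0, half - site_width + 1))
        shared_coords.append((seg.chrom, seg.start + offset))

    cistromes: dict[str, RegionSet] = {}
    for fi, factor in enumerate(factors):
        intervals: list[GenomicInterval] = []
        used_loss: list[int] = []
        if fi < 2 and shared_block:
            intervals += place(shared_idx, "loss", factor, "shared", shared_coords)
            used_loss = shared_idx.tolist()
        n_own = n_loss - (shared_block if fi < 2 else 0)
        remaining_w = loss_w.copy()
        remaining_w[used_loss] = 0.0
        remaining_w = remaining_w / remaining_w.sum()
        own_idx = rng.choice(n_segs, size=n_own, replace=False, p=remaining_w)
        intervals += place(own_idx, "loss", factor, "loss")
        gain_idx = rng.choice(n_segs, size=n_gain, replace=False)
        intervals += place(gain_idx, "gain", factor, "gain")
        cistromes[factor] = RegionSet(factor, intervals, config.genome_map)
    return cistromes, segmentation


# ---------------------------------------------------------------------------
# Gene models and DEG tables
# ---------------------------------------------------------------------------

def simulate_gene_models(
    config: SimulationConfig,
    class_probs: dict[str, float] | None = None,
    gene_length: int = 20_000,
) -> list[GeneModel]:
    """Random gene models: TSS uniform over the genome, random class labels."""
    class_probs = class_probs or GENE_CLASS_PROBS
    rng = config.rng("genes")
    chroms = [c for c, _ in config.genome]
    lengths = np.array([l for _, l in config.genome], dtype=float)
    chrom_p = lengths / lengths.sum()
    classes = list(class_probs)
    cls_p = np.array([class_probs[c] for c in classes], dtype=float)
    cls_p = cls_p / cls_p.sum()
    genes = []
    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        ci = int(rng.choice(len(chroms), p=chrom_p))
        tss = int(rng.integers(0, config.genome[ci][1] - gene_length))
        genes.append(
            GeneModel(
                f"G{i:0{width}d}",
                chroms[ci],
                tss,
                tss,
                tss + gene_length,
                classes[int(rng.choice(len(classes), p=cls_p))],
            )
        )
    return genes


def simulate_deg_table(
    config: SimulationConfig,
    gene_models: list[GeneModel],
    coupled_regions: RegionSet | None = None,
    coupling: float = 0.8,
    effect_mu: float = 1.0,
    null_sd: float = 0.05,
    window: int = 10_000,
) -> pd.DataFrame:
    """DEG table (gene, log2FC, logPV) with optional binding-loss coupling.

    log2FC is a null/DE mixture: null genes N(0, null_sd), DE genes
    sign * |N(effect_mu, lfc_sd)|. The p-value is the one implied by the
    z-statistic log2FC / null_sd, so the fold-change and significance
    thresholds stay jointly meaningful and null p-values are uniform.

    With ``coupled_regions``, DE genes whose TSS lies within ``window`` of
    a loss region are down-regulated with probability 0.5 + coupling / 2
    and their effect size is scaled by (1 + coupling) when down — loss of
    binding near a gene pushes it down, harder. ``coupling=0`` restores
    independence.
    """
    if not 0 <= coupling <= 1:
        raise ValueError("coupling must be in [0, 1]")
    from scipy.stats import norm

    rng = config.rng("deg")
    near_loss = {g.symbol: False for g in gene_models}
    if coupled_regions is not None:
        from .intervals import annotate_to_genes

        loss = coupled_regions.subset("loss")
        ann = annotate_to_genes(loss, gene_models, window=window)
        for g in set(ann["gene"]):
            near_loss[g] = True
    rows = []
    for g in gene_models:
        is_de = rng.random() < config.deg_fraction
        if not is_de:
            lfc = float(rng.normal(0.0, null_sd))
        else:
            if coupled_regions is not None and near_loss[g.symbol]:
                down = rng.random() < 0.5 + coupling / 2.0
                scale = (1.0 + coupling) if down else 1.0
            else:
                down = rng.random() < 0.5
                scale = 1.0
            magnitude = abs(rng.normal(effect_mu, config.lfc_sd)) * scale
            lfc = -magnitude if down else magnitude
        p = 2.0 * norm.sf(abs(lfc) / null_sd)
        rows.append(
            {
                "gene": g.symbol,
                "log2FC": lfc,
                "logPV": float(-np.log10(max(p, 1e-320))),
                "near_loss": near_loss[g.symbol],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NES tables
# ---------------------------------------------------------------------------

def simulate_nes_tables(
    config: SimulationConfig,
    n_terms: int = 500,
    keyword_pools: dict[str, list[str]] | None = None,
    switch_categories: list[str] | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two condition NES tables with a planted fraction of sign switches.

    Exactly ``round(switch_fraction * n_terms)`` terms are significant in
    both conditions with opposite NES sign; all other terms either share
    a sign or fail significance in at least one condition. Term names are
    built from the keyword pools so downstream keyword classification can
    be checked; ``switch_categories`` restricts which pools the switching
    terms draw from (non-switching terms then avoid those pools).
    """
    keyword_pools = keyword_pools or {
        "MYC": ["MYC"],
        "breast": ["BREAST"],
        "prostate": ["PROSTATE"],
        "nuclear receptor": ["ESTROGEN", "ANDROGEN"],
    }
    if any(not words for words in keyword_pools.values()):
        raise ValueError("keyword pools must be non-empty")
    rng = config.rng("nes")
    categories = list(keyword_pools)
    switch_cats = switch_categories if switch_categories is not None else categories
    other_cats = [c for c in categories if c not in switch_cats] or switch_cats
    n_switch = round(config.switch_fraction * n_terms)

    def make_term(i: int, pools: list[str]) -> str:
        cat = pools[int(rng.integers(len(pools)))]
        word = keyword_pools[cat][int(rng.integers(len(keyword_pools[cat])))]
        suffix = "".join(
            "ABCDEFGHIJKLMNOPQRSTUVWXYZ"[j] for j in rng.integers(0, 26, size=4)
        )
        return f"{word}_{suffix}_{i:04d}"

    rows_a, rows_b = [], []
    for i in range(n_terms):
        switching = i < n_switch
        term = make_term(i, switch_cats if switching else other_cats)
        library = "Hallmarks" if rng.random() < 0.5 else "C2-CGP"
        if switching:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            nes_a = sign * float(rng.uniform(1.5, 3.0))
            nes_b = -sign * float(rng.uniform(1.5, 3.0))
            padj_a = float(rng.uniform(0, alpha))
            padj_b = float(rng.uniform(0, alpha))
        else:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            nes_a = sign * float(rng.uniform(0.5, 3.0))
            nes_b = sign * float(rng.uniform(0.5, 3.0))
            if rng.random() < 0.5:  # significant in both, same sign
                padj_a = float(rng.uniform(0, alpha))
                padj_b = float(rng.uniform(0, alpha))
            else:  # insignificant in at least one
                padj_a = float(rng.uniform(alpha, 1))
                padj_b = float(rng.uniform(0, 1))
        rows_a.append({"term": term, "library": library, "NES": nes_a, "padj": padj_a})
        rows_b.append({"term": term, "library": library, "NES": nes_b, "padj": padj_b})
    return pd.DataFrame(rows_a), pd.DataFrame(rows_b)


# ---------------------------------------------------------------------------
# Tumor cohort
# ---------------------------------------------------------------------------

def simulate_cohort(
    config: SimulationConfig,
    signature_genes: list[str],
    shift: float = 3.0,
    category_strength: float = 0.9,
    ar_levels: tuple[str, ...] = ("AR_low", "AR_high"),
    ne_levels: tuple[str, ...] = ("NE_low", "NE_mid", "NE_high"),
) -> tuple[CohortMatrix, np.ndarray]:
    """Two-subtype genes x tumors Z-score cohort with AR/NE categories.

    Tumors split into two latent subtypes; half the signature genes are
    shifted up by ``shift`` standard deviations in subtype 1 (and the
    other half down), producing the block structure a clustered heatmap
    shows. Per-tumor AR and NE categories take the subtype-typical label
    with probability ``category_strength``, otherwise a uniform label.
    Returns the cohort and the true subtype vector (0/1 per tumor).
    """
    if config.n_tumors < 4:
        raise ValueError("need >= 4 tumors (>= 2 per subtype)")
    if not 0 <= category_strength <= 1:
        raise ValueError("category_strength must be in [0, 1]")
    rng = config.rng("cohort")
    n = config.n_tumors
    subtype = np.zeros(n, dtype=int)
    subtype[n // 2:] = 1
    rng.shuffle(subtype)
    genes = list(signature_genes)
    Z = rng.normal(0.0, 1.0, size=(len(genes), n))
    half = len(genes) // 2
    Z[:half, subtype == 0] += shift / 2.0
    Z[:half, subtype == 1] -= shift / 2.0
    Z[half:, subtype == 0] -= shift / 2.0
    Z[half:, subtype == 1] += shift / 2.0
    tumors = [f"T{i:03d}" for i in range(n)]

    def categories(levels: tuple[str, ...], typical_for_1: str) -> list[str]:
        out = []
        typical = {0: levels[0], 1: typical_for_1}
        for s in subtype:
            if rng.random() < category_strength:
                out.append(typical[s])
            else:
                out.append(levels[int(rng.integers(len(levels)))])
        return out

    # subtype 1 = AR-high / NE-low; subtype 0 = AR-low / NE-high
    ar = categories(ar_levels, ar_levels[-1])
    ne = categories(tuple(reversed(ne_levels)), ne_levels[0])
    cohort = CohortMatrix(
        pd.DataFrame(Z, index=genes, columns=tumors),
        pd.Series(ar, index=tumors, name="AR_category"),
        pd.Series(ne, index=tumors, name="NE_category"),
    )
    return cohort, subtype


# ---------------------------------------------------------------------------
# Region sequences with planted motifs
# ---------------------------------------------------------------------------

def simulate_sequences_with_motifs(
    config: SimulationConfig,
    regions: RegionSet,
    pwm: "PWM | list[PWM]",
    plant_rate: float,
    composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> dict[str, str]:
    """Background sequences for each region, with PWM consensuses planted.

    For each motif (one PWM or a list), its consensus is inserted at a
    random offset and strand into ``round(plant_rate * n_regions)``
    regions chosen without replacement (independently per motif).
    Returns region-name -> sequence. Region names must be unique and
    every region at least as long as the longest motif.
    """
    if not 0 <= plant_rate <= 1:
        raise ValueError("plant_rate must be in [0, 1]")
    from .motifs import BASES, _COMPLEMENT

    pwms = [pwm] if not isinstance(pwm, (list, tuple)) else list(pwm)
    rng = config.rng("sequences")
    names = [iv.name or f"{iv.chrom}:{iv.start}-{iv.end}" for iv in regions]
    if len(set(names)) != len(names):
        raise ValueError("region names must be unique")
    max_len = max(len(p) for p in pwms)
    comp = np.asarray(composition, dtype=float)
    comp = comp / comp.sum()
    seqs = {}
    for iv, name in zip(regions, names):
        if len(iv) < max_len:
            raise ValueError(f"region {name} shorter than motif ({max_len} bp)")
        seqs[name] = "".join(
            BASES[i] for i in rng.choice(4, size=len(iv), p=comp)
        )
    n_plant = round(plant_rate * len(names))
    for p in pwms:
        motif = p.consensus
        planted = rng.choice(len(names), size=n_plant, replace=False)
        for pi in planted:
            name = names[pi]
            seq = seqs[name]
            offset = int(rng.integers(0, len(seq) - len(motif) + 1))
            insert = motif
            if rng.random() < 0.5:
                insert = motif.translate(_COMPLEMENT)[::-1]
            seqs[name] = seq[:offset] + insert + seq[offset + len(insert):]
    return seqs


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def sequences_from_genome(fasta_path, regions: RegionSet) -> dict[str, str]:
    """Extract each region's sequence from a genome FASTA (via pyfaidx)."""
    from pyfaidx import Fasta

    genome = Fasta(str(fasta_path))
    out = {}
    for iv in regions:
        name = iv.name or f"{iv.chrom}:{iv.start}-{iv.end}"
        out[name] = str(genome[iv.chrom][iv.start:iv.end]).upper()
    return out


# ---------------------------------------------------------------------------
# Demo PWM set and synthetic cistrome collection
# ---------------------------------------------------------------------------

def demo_pwms(dominant: float = 0.91) -> list[PWM]:
    """A small sharp PWM set spanning the major motif families.

    Each motif concentrates ``dominant`` probability on its consensus
    base per position; sharp enough that a fraction-of-max threshold of
    0.9 has a negligible background hit rate at 200 bp.
    """

    def make(motif_id: str, factor: str, family: str, consensus: str) -> PWM:
        rest = (1.0 - dominant) / 3.0
        mat = np.full((len(consensus), 4), rest)
        for i, b in enumerate(consensus):
            mat[i, "ACGT".index(b)] = dominant
        return PWM(motif_id, factor, family, mat)

    return [
        make("M001", "ASCL1", "bHLH", "GGCAGCTGCC"),
        make("M002", "MYC", "bHLH", "GTCACGTGAC"),
        make("M003", "AR", "NR", "AGAACAGGCTGTTCT"),
        make("M004", "ESRRG", "NR", "TCAAGGTCAC"),
        make("M005", "ISL1", "Homeobox", "CCTAATTAGC"),
        make("M006", "NANOG", "Homeobox", "GCCATTAACA"),
        make("M007", "ELK4", "ETS", "ACCGGAAGTC"),
        make("M008", "NFYA", "MADS", "AGCCAATCAG"),
        make("M009", "SOX15", "SRY-box", "GAACAATGGC"),
    ]


def simulate_cistrome_collection(
    config: SimulationConfig,
    query: RegionSet,
    factors: list[str],
    datasets_per_factor: int = 20,
    regions_per_dataset: int = 300,
    enriched_factors: dict[str, float] | None = None,
    site_width: int = 400,
    tissue_tags: tuple[str, ...] = ("prostate", "breast", "blood"),
):
    """A synthetic reference cistrome collection for the co-enrichment scan.

    Datasets of factors listed in ``enriched_factors`` copy that fraction
    of their regions from the query set (planting genuine overlap); all
    other regions are uniform over the genome.
    """
    from .enrichment import CistromeCollection

    rng = config.rng("collection")
    enriched_factors = enriched_factors or {}
    chroms = [c for c, _ in config.genome]
    lengths = np.array([l for _, l in config.genome], dtype=float)
    chrom_p = lengths / lengths.sum()
    query_ivs = list(query.intervals)
    datasets = []
    for factor in factors:
        frac = enriched_factors.get(factor, 0.0)
        for d in range(datasets_per_factor):
            n_copy = int(round(frac * regions_per_dataset))
            ivs = []
            if n_copy and query_ivs:
                picks = rng.choice(len(query_ivs), size=min(n_copy, len(query_ivs)),
                                   replace=False)
                for qi in picks:
                    q = query_ivs[qi]
                    ivs.append(GenomicInterval(q.chrom, q.start, q.end, 1.0, "none"))
            for _ in range(regions_per_dataset - len(ivs)):
                ci = int(rng.choice(len(chroms), p=chrom_p))
                start = int(rng.integers(0, config.genome[ci][1] - site_width))
                ivs.append(
                    GenomicInterval(chroms[ci], start, start + site_width, 1.0, "none")
                )
            tissue = tissue_tags[int(rng.integers(len(tissue_tags)))]
            did = f"{factor}_{d:03d}"
            datasets.append(
                (did, factor, tissue, RegionSet(did, ivs, config.genome_map))
            )
    return CistromeCollection(datasets)
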