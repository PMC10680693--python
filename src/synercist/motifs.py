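"""PWM scanning and motif percentage-coverage deltas.

A motif hit in a region is called when the best log-odds window score on
either strand reaches a fraction (default 0.8) of the motif's maximum
attainable score. Coverage of a motif in a region set is the percentage
of regions with at least one hit; the delta between a treatment and a
reference set is the difference in percentage points. Deltas are finally
aggregated by transcription-factor family (bHLH, NR, Homeobox, ...) to
summarize which motif classes rose or fell.

Scoring: probabilities get a 0.01 pseudocount (then renormalized), the
window score is sum over positions of log2(p_base / background_base), and
windows containing N score -inf. Background defaults to uniform; pass the
region-set composition for a composition-matched scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PSEUDOCOUNT = 0.01


@dataclass
class PWM:
    """A position weight matrix with factor and family metadata.

    ``matrix`` is (length x 4) of base probabilities in A, C, G, T order;
    each row must sum to 1 (within 1e-6) and the motif must be at least
    4 bp long.
    """

    motif_id: str
    factor: str
    family: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (length x 4)")
        if self.matrix.shape[0] < 4:
            raise ValueError("motif length must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must each sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-6):
            raise ValueError("background frequencies must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(length x 5) log2 odds; column 4 (N) is -inf."""
        probs = self.matrix + PSEUDOCOUNT
        probs = probs / probs.sum(axis=1, keepdims=True)
        lo = np.log2(probs / self.background)
        return np.hstack([lo, np.full((len(self), 1), -np.inf)])

    @property
    def max_score(self) -> float:
        return float(self.log_odds[:, :4].max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


def read_jaspar(
    path, family_map: dict[str, str] | None = None, background=None
) -> list[PWM]:
    """Read PWMs from a JASPAR-format file (via Bio.motifs).

    ``family_map`` assigns families by motif id or factor name; unmapped
    motifs get family ``"other"``.
    """
    from Bio import motifs as bio_motifs

    family_map = family_map or {}
    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in BASES], dtype=float).T
            matrix = counts / counts.sum(axis=1, keepdims=True)
            name = m.name or m.matrix_id
            family = family_map.get(m.matrix_id, family_map.get(name, "other"))
            kwargs = {} if background is None else {"background": np.asarray(background)}
            out.append(PWM(m.matrix_id, name, family, matrix, **kwargs))
    return out


def write_jaspar(pwms: list[PWM], path, counts_scale: int = 100) -> None:
    """Write PWMs in JASPAR 2016 text format (probabilities x scale)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\t{pwm.factor}\n")
            for i, base in enumerate(BASES):
                vals = " ".join(
                    f"{v * counts_scale:10.2f}" for v in pwm.matrix[:, i]
                )
                fh.write(f"{base}  [ {vals} ]\n")


def _encode(sequence: str) -> np.ndarray:
    return np.fromiter(
        (_BASE_INDEX.get(b, 4) for b in sequence.upper()), dtype=np.int64,
        count=len(sequence),
    )


def scan_sequence(
    sequence: str, pwm: PWM, score_fraction: float = 0.8
) -> tuple[bool, float]:
    """Best log-odds window score over both strands; hit call.

    Returns ``(hit, best_score)`` where ``hit`` is True when the best
    window on either strand scores at least ``score_fraction`` times the
    motif's maximum attainable score. Windows containing N score -inf.
    """
    if not sequence:
        raise ValueError("empty sequence")
    L = len(pwm)
    if len(sequence) < L:
        raise ValueError(
            f"sequence length {len(sequence)} shorter than motif length {L}"
        )
    if not 0 < score_fraction <= 1:
        raise ValueError(f"score_fraction must be in (0, 1], got {score_fraction}")
    lo = pwm.log_odds
    best = -np.inf
    for seq in (sequence, sequence.translate(_COMPLEMENT)[::-1]):
        idx = _encode(seq)
        n_windows = len(idx) - L + 1
        # strided window view: windows x motif-length
        windows = np.lib.stride_tricks.sliding_window_view(idx, L)
        scores = lo[np.arange(L), windows].sum(axis=1)
        if n_windows:
            best = max(best, float(scores.max()))
    return best >= score_fraction * pwm.max_score, best


@dataclass
class MotifCoverage:
    """Fraction of a region set's regions containing a motif hit."""

    motif_id: str
    set_label: str
    n_regions: int
    n_with_hit: int

    @property
    def coverage_percent(self) -> float:
        return 100.0 * self.n_with_hit / self.n_regions if self.n_regions else 0.0


def coverage_percent(
    region_names: list[str],
    sequences: dict[str, str],
    pwm: PWM,
    set_label: str = "",
    score_fraction: float = 0.8,
) -> MotifCoverage:
    """Motif coverage of a region set: % of regions with >= 1 hit.

    ``sequences`` maps region name to nucleotide string; every region must
    have a sequence.
    """
    missing = [n for n in region_names if n not in sequences]
    if missing:
        raise ValueError(f"missing sequences for regions: {missing[:5]}")
    n_hit = sum(
        scan_sequence(sequences[n], pwm, score_fraction)[0] for n in region_names
    )
    return MotifCoverage(pwm.motif_id, set_label, len(region_names), n_hit)


def motif_delta(treatment: MotifCoverage, reference: MotifCoverage) -> float:
    """Signed coverage change, treatment minus reference (percentage points)."""
    if treatment.motif_id != reference.motif_id:
        raise ValueError(
            f"motif mismatch: {treatment.motif_id} vs {reference.motif_id}"
        )
    return treatment.coverage_percent - reference.coverage_percent


def family_frequency(
    deltas: dict[str, float],
    family_map: dict[str, str],
    threshold: float = 5.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Aggregate per-motif coverage deltas by transcription-factor family.

    Per family: number of motifs with delta >= +threshold, with delta <=
    -threshold, and the mean delta. Motifs absent from ``family_map`` are
    excluded and returned as the second element.
    """
    unmapped = sorted(m for m in deltas if m not in family_map)
    rows: dict[str, list[float]] = {}
    for motif, d in deltas.items():
        if motif in family_map:
            rows.setdefault(family_map[motif], []).append(d)
    out = []
    for family in sorted(rows):
        ds = np.array(rows[family])
        out.append(
            {
                "family": family,
                "n_motifs": len(ds),
                "n_up": int((ds >= threshold).sum()),
                "n_down": int((ds <= -threshold).sum()),
                "mean_delta": float(ds.mean()),
            }
        )
    return pd.DataFrame(out), unmapped
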