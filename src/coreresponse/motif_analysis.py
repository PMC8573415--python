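"""Position-weight-matrix scanning and co-motif enrichment.

The binding-site machinery: JASPAR count matrices become log-odds position
weight matrices; sequences are scanned on both strands and positions whose
score reaches a fraction of the matrix's maximal log-odds score (relative
score, default 0.8) are called sites. Around each called CDX-type site a
+/- 50 bp flanking window is cut, and a library of other transcription-factor
matrices is tested for over-representation in those windows against
length-matched sequences drawn uniformly from the genome, using ZOOPS
counting (a sequence contributes once if it contains at least one hit) and a
one-tailed Fisher exact test, Benjamini-Hochberg adjusted across the library.
Motifs carry TFclass-style class/family labels; a family-level Bonferroni
p-value (min member p x family size) is reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PWMModel", "MotifHit", "scan", "scan_library", "consensus",
    "flank_windows", "random_background", "estimate_background",
    "motif_enrichment", "write_hits_bed", "reverse_complement",
]

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC code for each subset of {A,C,G,T}
_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
    frozenset("ACG"): "V", frozenset("ACT"): "H", frozenset("AGT"): "D",
    frozenset("CGT"): "B", frozenset("ACGT"): "N",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to codes A=0 C=1 G=2 T=3; anything else -> -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in _CODE.items():
        codes[arr == ord(base)] = code
    return codes


@dataclass
class PWMModel:
    """A position frequency matrix with log-odds scoring parameters.

    ``counts`` is a 4 x L matrix, rows in A, C, G, T order. Column
    probabilities use ``(counts + pseudocount) / column_sum``; log-odds are
    log2(p / background). ``max_score`` / ``min_score`` are the column-wise
    maxima / minima sums, defining the relative score
    ``(score - min) / (max - min)`` in [0, 1].
    """

    motif_id: str
    name: str
    counts: np.ndarray
    pseudocount: float = 1.0
    background_freqs: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    tf_class: str = ""
    family: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4:
            raise ValueError("counts must have 4 rows (A, C, G, T)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.background_freqs = np.asarray(self.background_freqs, dtype=float)
        if self.background_freqs.shape != (4,):
            raise ValueError("background_freqs must be a 4-vector")
        if not math.isclose(self.background_freqs.sum(), 1.0, rel_tol=1e-6):
            raise ValueError("background_freqs must sum to 1")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        padded = self.counts + self.pseudocount
        return padded / padded.sum(axis=0, keepdims=True)

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probabilities / self.background_freqs[:, None])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())

    def with_background(self, background_freqs: np.ndarray) -> "PWMModel":
        return replace(self, background_freqs=np.asarray(background_freqs,
                                                         dtype=float))

    def relative_score(self, score: float) -> float:
        lo, hi = self.min_score, self.max_score
        if hi <= lo:        # fully degenerate matrix
            return 1.0
        return (score - lo) / (hi - lo)


@dataclass(frozen=True)
class MotifHit:
    """One called site: offset is bp from region start on the forward strand."""

    region_id: str
    offset: int
    strand: str
    score: float
    relative_score: float
    motif_id: str = ""

    @property
    def window_id(self) -> str:
        return f"{self.region_id}|{self.offset}|{self.strand}"


def consensus(pwm: PWMModel, min_freq: float = 0.25) -> str:
    """IUPAC consensus: per column, the code of bases at frequency >= min_freq
    after pseudocount."""
    probs = pwm.probabilities
    letters = []
    for col in probs.T:
        members = frozenset(b for b, p in zip(BASES, col) if p >= min_freq)
        if not members:                 # no base reaches the cut: most likely
            members = frozenset(BASES[int(np.argmax(col))])
        letters.append(_IUPAC[members])
    return "".join(letters)


def _strand_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Score every offset of one strand; windows touching N score -inf."""
    L = log_odds.shape[1]
    if codes.size < L:
        return np.empty(0)
    windows = sliding_window_view(codes, L)                 # (n_off, L)
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows >= 0, windows, 0)
    scores = log_odds[safe, np.arange(L)].sum(axis=1)
    scores[~valid] = -np.inf
    return scores


def scan(pwm: PWMModel, sequences: Mapping[str, str],
         relative_score_min: float = 0.8) -> list[MotifHit]:
    """Scan labelled sequences on both strands, emitting every position whose
    relative log-odds score reaches *relative_score_min*.

    The reverse strand is scanned by scoring with the reverse-complemented
    matrix, so a hit's offset always refers to the leftmost base of the site
    on the forward strand. Hits are sorted by (region, offset, strand).
    """
    lo, hi = pwm.min_score, pwm.max_score
    span = hi - lo
    fwd = pwm.log_odds
    rev = fwd[::-1, ::-1]               # complement bases, reverse positions
    hits: list[MotifHit] = []
    for region_id in sequences:
        codes = _encode(sequences[region_id])
        for strand, matrix in (("+", fwd), ("-", rev)):
            scores = _strand_scores(codes, matrix)
            if scores.size == 0:
                continue
            if span <= 0:
                rel = np.ones_like(scores)
                rel[~np.isfinite(scores)] = -np.inf
            else:
                rel = (scores - lo) / span
            for off in np.flatnonzero(rel >= relative_score_min):
                hits.append(MotifHit(
                    region_id=region_id, offset=int(off), strand=strand,
                    score=float(scores[off]), relative_score=float(rel[off]),
                    motif_id=pwm.motif_id))
    hits.sort(key=lambda h: (h.region_id, h.offset, h.strand))
    return hits


def scan_library(library: Sequence[PWMModel], sequences: Mapping[str, str],
                 relative_score_min: float = 0.8) -> dict[str, list[MotifHit]]:
    return {pwm.motif_id: scan(pwm, sequences, relative_score_min)
            for pwm in library}


def flank_windows(hits: Iterable[MotifHit], sequences: Mapping[str, str],
                  motif_length: int, flank_bp: int = 50) -> dict[str, str]:
    """Cut one window per hit spanning +/- flank_bp around the site, clipped
    to the region. Window ids inherit region, offset and strand."""
    windows: dict[str, str] = {}
    for hit in hits:
        seq = sequences[hit.region_id]
        left = max(0, hit.offset - flank_bp)
        right = min(len(seq), hit.offset + motif_length + flank_bp)
        windows[hit.window_id] = seq[left:right]
    return windows


def estimate_background(sequences: Mapping[str, str],
                        floor: float = 0.01) -> np.ndarray:
    """Base frequencies over a sequence set, floored and renormalised."""
    counts = np.zeros(4)
    for seq in sequences.values():
        codes = _encode(seq)
        counts += np.bincount(codes[codes >= 0], minlength=4)
    total = counts.sum()
    freqs = counts / total if total else np.full(4, 0.25)
    freqs = np.maximum(freqs, floor)
    return freqs / freqs.sum()


def random_background(genome: Mapping[str, str], template: Mapping[str, str],
                      seed: int | np.random.Generator = 0,
                      max_n_fraction: float = 0.5,
                      max_retries: int = 100) -> dict[str, str]:
    """Draw a background set matched to *template* in number and lengths.

    Start positions are uniform over all valid starts across chromosomes
    (chromosomes weighted by their number of valid starts for each length).
    Sequences with more than *max_n_fraction* N are redrawn, up to
    *max_retries* times.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    chroms = list(genome)
    lengths = np.array([len(genome[c]) for c in chroms])
    out: dict[str, str] = {}
    for i, (tid, tseq) in enumerate(template.items()):
        L = len(tseq)
        valid = np.maximum(lengths - L + 1, 0)
        if valid.sum() == 0:
            raise ValueError(
                f"no chromosome long enough for a {L} bp background sequence")
        weights = valid / valid.sum()
        for _ in range(max_retries):
            c = rng.choice(len(chroms), p=weights)
            start = int(rng.integers(0, valid[c]))
            seq = genome[chroms[c]][start:start + L]
            if L == 0 or seq.upper().count("N") / L <= max_n_fraction:
                out[f"bg_{i}_{chroms[c]}_{start}"] = seq
                break
        else:
            raise RuntimeError(
                f"could not place a background sequence of {L} bp after "
                f"{max_retries} retries (genome too N-rich?)")
    return out


def _haldane_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Odds ratio of [[a, b], [c, d]], +0.5 in every cell when any is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def motif_enrichment(library: Sequence[PWMModel],
                     foreground: Mapping[str, str],
                     background: Mapping[str, str],
                     relative_score_min: float = 0.8,
                     background_freqs: np.ndarray | None = None,
                     ) -> pd.DataFrame:
    """Test each motif for over-representation in foreground windows.

    ZOOPS counting: a window contributes 1 if it carries >= 1 hit on either
    strand (overlapping hits collapse automatically). The 2x2 table of
    with-hit / without-hit counts in foreground vs background is tested with
    the one-tailed (greater) Fisher exact test; BH adjustment across the
    library; family_p = min member p x family size (Bonferroni within the
    TFclass family), capped at 1.

    Returns a DataFrame with one row per motif: motif_id, name, tf_class,
    family, fg_regions_with_hit, fg_total, bg_regions_with_hit, bg_total,
    odds_ratio, p, p_adj, family_p.
    """
    if not foreground or not background:
        raise ValueError("foreground and background must be non-empty")
    if background_freqs is None:
        pooled = {**foreground, **{f"__bg_{k}": v
                                   for k, v in background.items()}}
        background_freqs = estimate_background(pooled)
    rows = []
    for pwm in library:
        model = pwm.with_background(background_freqs)
        fg_hit = len({h.region_id
                      for h in scan(model, foreground, relative_score_min)})
        bg_hit = len({h.region_id
                      for h in scan(model, background, relative_score_min)})
        fg_total, bg_total = len(foreground), len(background)
        table = [[fg_hit, fg_total - fg_hit], [bg_hit, bg_total - bg_hit]]
        p = float(stats.fisher_exact(table, alternative="greater")[1])
        rows.append({
            "motif_id": pwm.motif_id, "name": pwm.name,
            "tf_class": pwm.tf_class, "family": pwm.family,
            "fg_regions_with_hit": fg_hit, "fg_total": fg_total,
            "bg_regions_with_hit": bg_hit, "bg_total": bg_total,
            "odds_ratio": _haldane_odds_ratio(
                fg_hit, fg_total - fg_hit, bg_hit, bg_total - bg_hit),
            "p": p,
        })
    result = pd.DataFrame(rows)
    result["p_adj"] = multipletests(result["p"], method="fdr_bh")[1]
    family_size = result.groupby("family")["motif_id"].transform("size")
    family_min = result.groupby("family")["p"].transform("min")
    result["family_p"] = np.minimum(family_min * family_size, 1.0)
    result.loc[result["family"] == "", "family_p"] = np.nan
    return result


def write_hits_bed(hits: Iterable[MotifHit], motif_length: int,
                   path: str) -> None:
    """Write hits as BED6; the score column is relative_score x 1000."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join([
                h.region_id, str(h.offset), str(h.offset + motif_length),
                h.motif_id or "site", str(int(round(h.relative_score * 1000))),
                h.strand,
            ]) + "\n")
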