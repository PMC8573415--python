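import numpy as np
import pandas as pd
import pytest

from coreresponse import load_cdx_pwm
from coreresponse.io_formats import (GeneRecord, GenomeAnnotation,
                                     PeakCollection)


@pytest.fixture(scope="session")
def cdx_pwm():
    return load_cdx_pwm()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_annotation():
    """Six genes on two chromosomes, mixed strands and biotypes."""
    genes = [
        GeneRecord("gA", "chr1", 5000, 8000, "+", "protein_coding"),
        GeneRecord("gB", "chr1", 12000, 14000, "-", "protein_coding"),
        GeneRecord("gC", "chr1", 20000, 21000, "+", "non_coding"),
        GeneRecord("gD", "chr2", 1000, 2000, "-", "protein_coding"),
        GeneRecord("gE", "chr2", 9000, 9500, "+", "non_coding"),
        GeneRecord("gF", "chr2", 15000, 18000, "+", "protein_coding"),
    ]
    return GenomeAnnotation(genes, chrom_lengths={"chr1": 30000,
                                                  "chr2": 25000})


def random_collection(rng, label, n_peaks=200, genome_len=200_000,
                      min_len=50, max_len=500, chroms=("chr1",)):
    starts = rng.integers(0, genome_len - max_len, size=n_peaks)
    lengths = rng.integers(min_len, max_len, size=n_peaks)
    return PeakCollection(label=label, df=pd.DataFrame({
        "chrom": rng.choice(list(chroms), size=n_peaks),
        "start": starts,
        "end": starts + lengths,
        "name": [f"{label}_{i}" for i in range(n_peaks)],
    }))


def naive_scan_oracle(pwm, sequences, relative_score_min):
    """Independent per-offset, per-strand rescoring from the raw counts."""
    import math
    L = pwm.length
    bg = {b: float(f) for b, f in zip("ACGT", pwm.background_freqs)}
    cols = []
    for j in range(L):
        colsum = sum(pwm.counts[i][j] + pwm.pseudocount for i in range(4))
        cols.append({b: math.log2(
            ((pwm.counts[i][j] + pwm.pseudocount) / colsum) / bg[b])
            for i, b in enumerate("ACGT")})
    hi = sum(max(c.values()) for c in cols)
    lo = sum(min(c.values()) for c in cols)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    hits = []
    for rid, seq in sequences.items():
        seq = seq.upper()
        for off in range(len(seq) - L + 1):
            window = seq[off:off + L]
            if any(b not in "ACGT" for b in window):
                continue
            fwd = sum(cols[j][window[j]] for j in range(L))
            rev = sum(cols[j][comp[window[L - 1 - j]]] for j in range(L))
            for strand, score in (("+", fwd), ("-", rev)):
                rel = 1.0 if hi == lo else (score - lo) / (hi - lo)
                if rel >= relative_score_min:
                    hits.append((rid, off, strand, score))
    return hits


def hypergeom_tail_oracle(k, m, n, N):
    """Exact integer tail sum P(X >= k) for overlap of an m-set and an
    n-set inside an N-universe."""
    import math
    total = math.comb(N, m)
    tail = sum(math.comb(n, i) * math.comb(N - n, m - i)
               for i in range(k, min(m, n) + 1))
    return tail / total


def per_base_core_oracle(collections, genome_len, min_overlap_bp,
                         chroms=("chr1",)):
    """Brute force: mark bases covered in every collection, extract runs."""
    regions = []
    for chrom in chroms:
        masks = []
        for coll in collections:
            mask = np.zeros(genome_len, dtype=bool)
            sub = coll.df[coll.df["chrom"] == chrom]
            for s, e in zip(sub["start"], sub["end"]):
                mask[s:e] = True
            masks.append(mask)
        common = np.logical_and.reduce(masks)
        padded = np.concatenate([[False], common, [False]]).astype(int)
        edges = np.flatnonzero(np.diff(padded))
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s >= min_overlap_bp:
                regions.append((chrom, int(s), int(e)))
    return regions
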