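"""Overlap statistics and promoter motif enrichment.

Two questions are answered here: how much of an external gene signature
(e.g. a stem-cell-niche gene set) is contained in the curated stroma
transcriptome (one-sided hypergeometric test plus coverage), and whether a
transcription-factor binding motif is over-represented in the promoters of a
gene cluster relative to same-size random draws from a background gene pool
(enrichment factor with a resampling p-value).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import motifs as bio_motifs
from scipy import stats

from . import _sequence as sq

PWM_PSEUDOCOUNT = 1e-3
DEFAULT_SCORE_FRACTION = 0.8
# the emulated study reports motifs with enrichment factors from 1.2 up and
# resampling p-values below 1e-4
REPORT_EF_MIN = 1.2
REPORT_P_MAX = 1e-4


@dataclass
class OverlapResult:
    """Hypergeometric overlap of a query gene list with a signature."""

    k: int  # overlap
    K: int  # signature size within the universe
    n: int  # query size
    N: int  # universe size
    p: float  # one-sided upper-tail hypergeometric probability
    fold: float  # (k/n) / (K/N)

    @property
    def coverage(self) -> float:
        """Percent of the signature contained in the query."""
        return 100.0 * self.k / self.K if self.K else 0.0

    @property
    def coverage_display(self) -> str:
        return f"{self.coverage:.1f}%"


def overlap_test(
    query: Iterable[str], signature: Iterable[str], universe: Iterable[str]
) -> OverlapResult:
    """One-sided hypergeometric upper-tail test of query/signature overlap.

    The signature is first restricted to the universe; the query must be a
    subset of the universe.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query)
    if q - uni:
        raise ValueError("query contains genes outside the universe")
    sig = set(signature) & uni
    k = len(q & sig)
    K, n, N = len(sig), len(q), len(uni)
    # upper tail including the observed count; k = 0 gives p = 1
    p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
    expected = K / N * n
    fold = (k / n) / (K / N) if n and K else 0.0
    return OverlapResult(k=k, K=K, n=n, N=N, p=min(p, 1.0), fold=fold)


# ---------------------------------------------------------------------------
# motifs


@dataclass
class MotifModel:
    """A position weight matrix over ACGT with a relative score threshold.

    ``pwm`` rows are positions, columns A/C/G/T probabilities (each row sums
    to 1).  A window is a hit when its log-odds score against a uniform
    background reaches ``score_fraction`` of the maximum achievable score;
    a pseudocount is added to the columns before taking logs.
    """

    name: str
    pwm: np.ndarray
    score_fraction: float = DEFAULT_SCORE_FRACTION

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=np.float64)
        if self.pwm.ndim != 2 or self.pwm.shape[1] != 4:
            raise ValueError("pwm must be (width, 4)")
        if self.width < 4:
            raise ValueError("motif width must be >= 4")
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("pwm columns must sum to 1")
        if not 0 < self.score_fraction <= 1:
            raise ValueError("score_fraction must be in (0, 1]")

    @property
    def width(self) -> int:
        return self.pwm.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        p = self.pwm + PWM_PSEUDOCOUNT
        p /= p.sum(axis=1, keepdims=True)
        return np.log2(p / 0.25)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def threshold(self) -> float:
        return self.score_fraction * self.max_score

    @property
    def consensus(self) -> str:
        return "".join(sq.ALPHABET[i] for i in self.pwm.argmax(axis=1))


def read_motifs(path: str | Path, fmt: str | None = None) -> list[MotifModel]:
    """Read PWMs from MEME-minimal or TRANSFAC-matrix text (auto-detected)."""
    text = Path(path).read_text()
    if fmt is None:
        fmt = "minimal" if "MEME version" in text else "transfac"
    records = bio_motifs.parse(_io.StringIO(text), fmt)
    models = []
    for j, m in enumerate(records):
        counts = np.array([[m.counts[b][i] for b in "ACGT"] for i in range(m.length)],
                          dtype=np.float64)
        total = counts.sum(axis=1, keepdims=True)
        name = getattr(m, "name", None)
        if not name and hasattr(m, "get"):  # TRANSFAC records are dict-like
            name = m.get("ID") or m.get("AC")
        models.append(MotifModel(name=name or f"motif_{j}", pwm=counts / total))
    return models


def write_motifs_meme(models: Sequence[MotifModel], path: str | Path) -> None:
    """Write PWMs in MEME minimal format."""
    lines = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", "",
             "Background letter frequencies", "A 0.25 C 0.25 G 0.25 T 0.25", ""]
    for m in models:
        lines.append(f"MOTIF {m.name}")
        lines.append(f"letter-probability matrix: alength= 4 w= {m.width} nsites= 20 E= 0")
        for row in m.pwm:
            lines.append(" " + " ".join(f"{v:.6f}" for v in row))
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def scan_motif(sequence: str, motif: MotifModel) -> int:
    """Number of windows (both strands) scoring at or above the motif
    threshold.  Windows containing N score as non-hits."""
    if len(sequence) < motif.width:
        raise ValueError("sequence shorter than motif")
    if set(sequence) - set("ACGTN"):
        raise ValueError("non-ACGTN characters in sequence")
    lo = motif.log_odds
    w = motif.width
    total = 0
    for strand_seq in (sequence, sq.revcomp(sequence)):
        enc = sq.encode(strand_seq)
        n_win = len(enc) - w + 1
        windows = np.lib.stride_tricks.sliding_window_view(enc, w)
        valid = (windows < 4).all(axis=1)
        safe = np.where(windows < 4, windows, 0)
        scores = lo[np.arange(w)[None, :], safe].sum(axis=1)
        total += int(np.count_nonzero(valid & (scores >= motif.threshold - 1e-12)))
    return total


@dataclass
class MotifEnrichmentResult:
    """Enrichment of a motif in a gene cluster's promoters versus matched
    random background draws."""

    motif: str
    ef: float  # freq_cluster / mean resampled background frequency
    p: float  # (1 + #{resamples >= observed}) / (n_resamples + 1)
    freq_cluster: float
    freq_background: float
    n_resamples: int
    seed: int
    reported: bool = field(init=False)

    def __post_init__(self) -> None:
        self.reported = (self.ef >= REPORT_EF_MIN) and (self.p < REPORT_P_MAX)


def motif_enrichment(
    cluster: Sequence[str],
    background_pool: Sequence[str],
    promoters: Mapping[str, str],
    motif: MotifModel,
    n_resamples: int = 10_000,
    seed: int = 0,
    with_replacement: bool = True,
) -> MotifEnrichmentResult:
    """Resampling test for motif over-representation in cluster promoters.

    ``freq`` is the fraction of genes with at least one promoter hit.  Each
    resample draws ``len(cluster)`` genes from the background pool (bootstrap
    draws by default, so the pool may be no larger than the cluster); the
    enrichment factor is the cluster frequency over the mean resampled
    frequency and the p-value uses the add-one Monte-Carlo convention, so it
    is never exactly zero and has resolution 1/(n_resamples + 1).
    """
    cluster = list(cluster)
    pool = list(background_pool)
    if set(cluster) & set(pool):
        raise ValueError("cluster genes must be excluded from the background pool")
    if not with_replacement and len(cluster) > len(pool):
        raise ValueError("cluster larger than background pool: resampling infeasible")
    missing = (set(cluster) | set(pool)) - set(promoters)
    if missing:
        raise ValueError(f"missing promoters for {len(missing)} genes (e.g. {sorted(missing)[:3]})")

    cluster_hits = np.array([scan_motif(promoters[g], motif) > 0 for g in cluster])
    pool_hits = np.array([scan_motif(promoters[g], motif) > 0 for g in pool])
    freq_cluster = float(cluster_hits.mean())

    rng = np.random.default_rng(seed)
    m = len(cluster)
    if with_replacement:
        idx = rng.integers(0, len(pool), size=(n_resamples, m))
        freqs = pool_hits[idx].mean(axis=1)
    else:
        freqs = np.empty(n_resamples)
        for i in range(n_resamples):
            freqs[i] = pool_hits[rng.choice(len(pool), size=m, replace=False)].mean()
    mean_bg = float(freqs.mean())
    ef = freq_cluster / mean_bg if mean_bg > 0 else np.inf if freq_cluster > 0 else 0.0
    p = float((1 + np.count_nonzero(freqs >= freq_cluster - 1e-12)) / (n_resamples + 1))
    return MotifEnrichmentResult(
        motif=motif.name,
        ef=float(ef),
        p=p,
        freq_cluster=freq_cluster,
        freq_background=mean_bg,
        n_resamples=n_resamples,
        seed=seed,
    )
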