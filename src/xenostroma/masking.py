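"""Cross-species probe masking.

In a human-cancer-in-mouse-bone xenograft, the stroma (mouse) transcriptome
is profiled on a mouse array while abundant human cancer-cell RNA is present
in the same hybridization mix.  Any probe whose sequence matches a human
transcript well enough picks up off-target signal, so probe-sets are
redefined to keep only species-specific probes before summarization.

A probe is flagged as cross-hybridizing when either

* its longest contiguous exact match to any off-target transcript (either
  strand) is >= ``l_min`` nucleotides, or
* its best full-length ungapped identity at any offset (either strand) is
  >= ``i_min``,

or when it contains ambiguous bases (N), which are masked conservatively.
Both criteria are computed exactly: contiguous matches via packed k-mer
membership at every word size from the probe length downwards, identity via
exhaustive XOR/popcount comparison of the probe (and its reverse complement)
against every off-target window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _sequence as sq
from .chip import ChipDefinition, MaskedChipDefinition

DEFAULT_L_MIN = 15
DEFAULT_I_MIN = 0.80
DEFAULT_MIN_PROBES = 4


@dataclass
class CrossHybReport:
    """Per-probe cross-hybridization scores and flag decisions."""

    table: pd.DataFrame  # probe_id-indexed: probeset_id, match_len, identity, flagged, partner
    params: dict = field(default_factory=dict)

    def flagged_probes(self) -> set[str]:
        return set(self.table.index[self.table["flagged"]])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CrossHybReport":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df["flagged"] = df["flagged"].astype(bool)
        return cls(df)


def _validate_sequences(transcripts: Mapping[str, str]) -> None:
    for name, seq in transcripts.items():
        if set(seq) - set("ACGTN"):
            raise ValueError(f"non-ACGTN characters in transcript {name}")


def _concat_offtarget(transcripts: Mapping[str, str]) -> np.ndarray:
    """Encoded concatenation of all transcripts with N separators."""
    parts: list[str] = []
    for seq in transcripts.values():
        parts.append(seq)
        parts.append("N")
    return sq.encode("".join(parts)) if parts else np.empty(0, dtype=np.uint8)


def _encode_matrix(probes: Sequence[str]) -> np.ndarray:
    lengths = {len(p) for p in probes}
    if len(lengths) != 1:
        raise ValueError("probes must have a single fixed length")
    return np.vstack([sq.encode(p) for p in probes])


def _rolling_codes(mat: np.ndarray, k: int) -> np.ndarray:
    """Packed codes of every k-mer of every row, shape (n, L - k + 1)."""
    n, L = mat.shape
    base = mat.astype(np.uint64)
    codes = np.zeros((n, L - k + 1), dtype=np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | base[:, j : L - k + 1 + j]
    return codes


def _longest_matches(
    probe_mat: np.ndarray, enc_text: np.ndarray, both_strands: bool
) -> np.ndarray:
    """Exact longest contiguous match per probe row against the encoded text.

    Descends through word sizes: at each k, probes not yet resolved are tested
    for membership of any of their k-mers (and reverse-complement k-mers when
    ``both_strands``) in the sorted set of text k-mers.
    """
    n, L = probe_mat.shape
    if L > 32:
        raise ValueError("probe length > 32 nt not supported by the packed scanner")
    rc_mat = (3 - probe_mat[:, ::-1]).astype(np.uint8) if both_strands else None
    match_len = np.zeros(n, dtype=np.int64)
    unresolved = np.arange(n)
    for k in range(L, 0, -1):
        if unresolved.size == 0:
            break
        text_k = np.unique(sq.kmer_codes(enc_text, k))
        if text_k.size == 0:
            continue
        pk = _rolling_codes(probe_mat[unresolved], k)
        hit = np.isin(pk, text_k).any(axis=1)
        if both_strands:
            rk = _rolling_codes(rc_mat[unresolved], k)
            hit |= np.isin(rk, text_k).any(axis=1)
        match_len[unresolved[hit]] = k
        unresolved = unresolved[~hit]
    return match_len


def longest_offtarget_match(
    probe: str,
    offtarget: Mapping[str, str] | Sequence[str],
    both_strands: bool = True,
) -> int:
    """Length of the longest substring of ``probe`` (or, by default, of its
    reverse complement too) occurring exactly in any off-target transcript.

    Returns 0 for an empty transcript set.
    """
    if isinstance(offtarget, Mapping):
        transcripts = dict(offtarget)
    else:
        transcripts = {f"t{i}": s for i, s in enumerate(offtarget)}
    if not probe:
        raise ValueError("probe must be non-empty")
    if set(probe) - set("ACGT"):
        raise ValueError("non-ACGT characters in probe")
    _validate_sequences(transcripts)
    if not transcripts:
        return 0
    enc_text = _concat_offtarget(transcripts)
    return int(_longest_matches(_encode_matrix([probe]), enc_text, both_strands)[0])


def _find_partner(probe: str, match_len: int, transcripts: Mapping[str, str]) -> str | None:
    """Locate one off-target transcript containing the best contiguous match."""
    if match_len == 0:
        return None
    candidates = {probe[i : i + match_len] for i in range(len(probe) - match_len + 1)}
    rc = sq.revcomp(probe)
    candidates |= {rc[i : i + match_len] for i in range(len(rc) - match_len + 1)}
    for name, seq in transcripts.items():
        if any(sub in seq for sub in candidates):
            return name
    return None


def scan_cross_hybridization(
    chipdef: ChipDefinition,
    offtarget: Mapping[str, str],
    l_min: int = DEFAULT_L_MIN,
    i_min: float = DEFAULT_I_MIN,
    both_strands: bool = True,
) -> CrossHybReport:
    """Score every probe of the chip against the off-target transcriptome.

    Parameters
    ----------
    l_min : contiguous-match flag threshold (nt), 1 <= l_min <= probe length.
    i_min : full-probe ungapped identity flag threshold, in (0, 1].
    both_strands : also scan the reverse complement of each probe (default);
        cRNA targets can cross-hybridize in either orientation relative to the
        stored transcript sequence.
    """
    if not chipdef.probesets:
        raise ValueError("empty chip definition")
    _validate_sequences(offtarget)
    probe_ids: list[str] = []
    probeset_ids: list[str] = []
    seqs: list[str] = []
    for ps, probes in chipdef.probesets.items():
        for pid, seq in probes:
            probe_ids.append(pid)
            probeset_ids.append(ps)
            seqs.append(seq)
    plen = len(seqs[0])
    if any(len(s) != plen for s in seqs):
        raise ValueError("probes must have a single fixed length")
    if not 1 <= l_min <= plen:
        raise ValueError(f"l_min must be in [1, {plen}]")
    if not 0 < i_min <= 1:
        raise ValueError("i_min must be in (0, 1]")

    has_n = np.array(["N" in s for s in seqs])
    # placeholder rows keep the matrix rectangular; N probes are flagged anyway
    clean = [s if "N" not in s else "A" * plen for s in seqs]

    if offtarget:
        enc_text = _concat_offtarget(offtarget)
        probe_mat = _encode_matrix(clean)
        match_len = _longest_matches(probe_mat, enc_text, both_strands)
        win_codes = sq.kmer_codes(enc_text, plen)
        probe_codes = _rolling_codes(probe_mat, plen)[:, 0]
        identity = sq.best_identity(probe_codes, win_codes, plen)
        if both_strands:
            rc_codes = _rolling_codes((3 - probe_mat[:, ::-1]).astype(np.uint8), plen)[:, 0]
            identity = np.maximum(identity, sq.best_identity(rc_codes, win_codes, plen))
    else:
        match_len = np.zeros(len(seqs), dtype=np.int64)
        identity = np.zeros(len(seqs), dtype=np.float64)

    match_len = np.where(has_n, 0, match_len)
    identity = np.where(has_n, 0.0, identity)
    flagged = (match_len >= l_min) | (identity >= i_min) | has_n

    partners: list[str | None] = [None] * len(seqs)
    if offtarget:
        for i in np.nonzero(flagged & ~has_n)[0]:
            partners[i] = _find_partner(seqs[i], int(match_len[i]), offtarget)

    table = pd.DataFrame(
        {
            "probeset_id": probeset_ids,
            "match_len": match_len,
            "identity": identity,
            "flagged": flagged,
            "partner": partners,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return CrossHybReport(
        table, params={"l_min": l_min, "i_min": i_min, "both_strands": both_strands}
    )


def redefine_probesets(
    chipdef: ChipDefinition,
    report: CrossHybReport,
    min_probes: int = DEFAULT_MIN_PROBES,
) -> MaskedChipDefinition:
    """Remove flagged probes; drop probe-sets left with < ``min_probes``.

    Probe order within each surviving probe-set is preserved.
    """
    flagged = report.flagged_probes()
    all_probe_ids = {pid for probes in chipdef.probesets.values() for pid, _ in probes}
    missing = all_probe_ids - set(report.table.index)
    if missing:
        raise ValueError(
            f"report does not cover {len(missing)} probes (e.g. {sorted(missing)[:3]})"
        )

    retained: dict[str, list[str]] = {}
    dropped: list[tuple[str, str]] = []
    for ps, probes in chipdef.probesets.items():
        keep = [pid for pid, _ in probes if pid not in flagged]
        if len(keep) == 0:
            dropped.append((ps, "all probes cross-hybridizing"))
        elif len(keep) < min_probes:
            dropped.append((ps, f"fewer than {min_probes} species-specific probes"))
        else:
            retained[ps] = keep
    params = dict(report.params)
    params["min_probes"] = min_probes
    return MaskedChipDefinition(retained, dropped, params)
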