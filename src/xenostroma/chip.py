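"""Chip-definition containers: probe-set layouts before and after masking.

A :class:`ChipDefinition` maps each probe-set (one per gene) to its ordered
short oligo probes, mirroring an Affymetrix-style CDF reduced to what the
masking and summarization stages need.  A :class:`MaskedChipDefinition` is
the species-specific redefinition: per probe-set, the retained probe ids,
plus a record of probe-sets dropped outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

_VALID = set("ACGTN")


@dataclass
class ChipDefinition:
    """probeset_id -> ordered list of (probe_id, sequence)."""

    probesets: dict[str, list[tuple[str, str]]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ps, probes in self.probesets.items():
            for pid, seq in probes:
                if not seq:
                    raise ValueError(f"empty probe sequence: {pid}")
                if set(seq) - _VALID:
                    raise ValueError(f"non-ACGTN characters in probe {pid}")
                if pid in seen:
                    raise ValueError(f"duplicate probe id: {pid}")
                seen.add(pid)

    @property
    def n_probes(self) -> int:
        return sum(len(p) for p in self.probesets.values())

    def probe_table(self) -> pd.DataFrame:
        rows = [
            (ps, pid, idx, seq)
            for ps, probes in self.probesets.items()
            for idx, (pid, seq) in enumerate(probes)
        ]
        return pd.DataFrame(rows, columns=["probeset_id", "probe_id", "probe_index", "sequence"])

    def to_tsv(self, path: str | Path) -> None:
        self.probe_table().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ChipDefinition":
        df = pd.read_csv(path, sep="\t", comment="#")
        probesets: dict[str, list[tuple[str, str]]] = {}
        for ps, grp in df.groupby("probeset_id", sort=False):
            grp = grp.sort_values("probe_index")
            probesets[str(ps)] = list(zip(grp["probe_id"].astype(str), grp["sequence"].astype(str)))
        return cls(probesets)


@dataclass
class MaskedChipDefinition:
    """Species-specific probe-set redefinition after cross-hyb masking."""

    probesets: dict[str, list[str]]  # probeset_id -> retained probe ids (order preserved)
    dropped_probesets: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)
    params: dict = field(default_factory=dict)  # l_min, i_min, min_probes

    @property
    def retained_probe_ids(self) -> list[str]:
        return [pid for probes in self.probesets.values() for pid in probes]

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (ps, pid, idx, "retained")
            for ps, probes in self.probesets.items()
            for idx, pid in enumerate(probes)
        ]
        rows += [(ps, "", -1, f"dropped: {reason}") for ps, reason in self.dropped_probesets]
        df = pd.DataFrame(rows, columns=["probeset_id", "probe_id", "probe_index", "status"])
        header = [f"{k}={v}" for k, v in self.params.items()]
        with open(path, "w") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MaskedChipDefinition":
        params: dict = {}
        with open(path) as fh:
            lines = fh.readlines()
        for line in lines:
            if line.startswith("# ") and "=" in line:
                k, v = line[2:].strip().split("=", 1)
                try:
                    params[k] = float(v) if "." in v else int(v)
                except ValueError:
                    params[k] = v
        df = pd.read_csv(path, sep="\t", comment="#")
        probesets: dict[str, list[str]] = {}
        dropped: list[tuple[str, str]] = []
        for _, row in df.iterrows():
            if str(row["status"]).startswith("dropped"):
                dropped.append((str(row["probeset_id"]), str(row["status"])[9:]))
            else:
                probesets.setdefault(str(row["probeset_id"]), []).append(str(row["probe_id"]))
        return cls(probesets, dropped, params)
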