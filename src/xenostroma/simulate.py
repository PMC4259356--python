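"""Synthetic two-species xenograft data with known ground truth.

The generator emulates the measurement problem of profiling mouse bone
stroma on a mouse array while human cancer-cell RNA is present in the same
hybridization: two divergent transcript sets, an Affymetrix-style chip whose
probes are exact substrings of the mouse transcripts, a controlled minority
of probes that cross-hybridize to one human transcript, group/replicate
structure with per-model human:mouse RNA mixing ratios, a minority of truly
differentially expressed stroma genes, a registry of "published" signatures
with planted overlap structure, and promoter sequences with planted motif
occurrences.

Sequences are i.i.d. uniform ACGT.  Species specificity is enforced
constructively: every unplanted probe is rejection-sampled so that it shares
no 12-mer (on either strand) with the human transcript set or with any other
probe, which bounds its longest off-target contiguous match below 12 nt.
Cross-hybridizing probes are planted by copying a contiguous probe window of
known length (>= the masking threshold) into one human transcript, with the
junction sequence re-checked so no other probe acquires an off-target match.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _sequence as sq
from .chip import ChipDefinition

SPECIFICITY_KMER = 12  # no unplanted probe shares a word this long with the off-target set
JUNCTION_MARGIN = SPECIFICITY_KMER - 1

DE_GROUPS = ("C4-2B", "VCaP")  # osteoinductive xenograft models carrying the stroma response
CATEGORY_ORDER = ("inflammatory", "non-osteotropic-cancer", "osteotropic-primary")

# named signatures emitted per curation category, mirroring the kinds of
# published gene lists subtracted during curation
CATEGORY_SIGNATURES = {
    "inflammatory": ("desmoplastic_response", "wound_healing", "inflammatory_response"),
    "non-osteotropic-cancer": ("gastric_stroma", "pancreatic_stroma", "colorectal_stroma"),
    "osteotropic-primary": ("primary_mammary_stroma", "primary_prostate_stroma"),
}


class InfeasibleSimulationError(RuntimeError):
    """Rejection sampling exhausted its attempt budget: the requested probe
    density cannot be packed into the available sequence space."""


def parse_ratio(ratio: str | float) -> float:
    """Convert a human:mouse ratio ('1:5' or a float h/m) to float h/m."""
    if isinstance(ratio, str):
        h, m = ratio.split(":")
        return float(h) / float(m)
    return float(ratio)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic xenograft experiment.

    Mixing ratios are the measured human:mouse RNA ratios of the emulated
    study (1:1 for C4-2B, 1:5 for VCaP, 1:9 for PC-3 intra-osseous
    xenografts, 4:1 subcutaneous, 1:2 orthotopic); replicate structure is
    three per group except sham bones and Ep156T control xenografts (two).
    """

    n_genes_per_species: int = 1000
    probes_per_set: int = 11
    probe_length: int = 25
    frac_de: float = 0.10
    effect_size: tuple[float, float] = (1.5, 0.3)  # mean, sd of |log2FC|
    frac_crosshyb_probes: float = 0.05
    contamination_coef: float = 0.25  # fraction of off-target abundance bleeding in
    mixing_ratios: dict[str, str] = field(
        default_factory=lambda: {
            "C4-2B": "1:1",
            "VCaP": "1:5",
            "PC-3": "1:9",
            "subcutaneous": "4:1",
            "orthotopic": "1:2",
        }
    )
    replicates: dict[str, int] = field(
        default_factory=lambda: {
            "C4-2B": 3,
            "VCaP": 3,
            "PC-3": 3,
            "intact": 3,
            "sham": 2,
            "Ep156T": 2,
        }
    )
    noise_sd: float = 0.25
    seed: int = 0

    # generator internals, all config-exposed
    min_planted_match: int = 15  # planted off-target matches start at the masking threshold
    # cross-hybridization clusters within genes (a mouse gene with a close
    # human homolog tends to have many affected probes); planting walks genes
    # and plants each of their probes with this rate until the budget is met
    crosshyb_gene_clustered: bool = True
    crosshyb_within_gene_rate: float = 0.5
    min_effect: float = 0.5  # |log2FC| floor
    frac_up: float = 0.64  # share of DE genes up-regulated in xenografts
    human_transcript_nt: int = 120
    spacer_nt: int = 5
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    category_overlap: dict[str, float] = field(
        default_factory=lambda: {
            "inflammatory": 0.10,
            "non-osteotropic-cancer": 0.08,
            "osteotropic-primary": 0.09,
        }
    )
    signature_filler: int = 30  # non-DE genes padded into each category signature
    niche_signatures: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"HSC-niche": (31, 14), "UGM-niche": (140, 21)}
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("frac_de", "frac_crosshyb_probes", "contamination_coef", "frac_up"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_genes_per_species", "probes_per_set", "probe_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.probe_length > 32:
            raise ValueError("probe_length > 32 not supported")
        if self.min_planted_match > self.probe_length:
            raise ValueError("min_planted_match exceeds probe_length")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for grp, n in self.replicates.items():
            if n < 1:
                raise ValueError(f"replicates[{grp}] must be >= 1")

    def group_ratio(self, group: str) -> float:
        """Human:mouse RNA ratio (as h/m) for a sample group."""
        if group in self.mixing_ratios:
            return parse_ratio(self.mixing_ratios[group])
        if group in ("sham", "intact"):
            return 0.0
        if group == "Ep156T":
            # non-tumorigenic control cells: minor human content
            return parse_ratio("1:9")
        raise KeyError(f"unknown group name: {group}")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["effect_size"] = list(self.effect_size)
        d["niche_signatures"] = {k: list(v) for k, v in self.niche_signatures.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "effect_size" in d:
            d["effect_size"] = tuple(d["effect_size"])
        if "niche_signatures" in d:
            d["niche_signatures"] = {k: tuple(v) for k, v in d["niche_signatures"].items()}
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted facts every downstream stage is checked against."""

    de_genes: dict[str, float]  # mouse symbol -> signed true log2FC
    crosshyb_probes: dict[str, int]  # probe_id -> planted off-target match length (nt)
    crosshyb_partner: dict[str, str]  # probe_id -> human transcript id
    signature_memberships: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "de_genes": self.de_genes,
                    "crosshyb_probes": self.crosshyb_probes,
                    "crosshyb_partner": self.crosshyb_partner,
                    "signature_memberships": self.signature_memberships,
                },
                fh,
                sort_keys=True,
                indent=2,
            )
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            d["de_genes"], d["crosshyb_probes"], d["crosshyb_partner"],
            d.get("signature_memberships", {}),
        )


@dataclass
class ReferenceBundle:
    mouse_transcripts: dict[str, str]
    human_transcripts: dict[str, str]
    chipdef: ChipDefinition
    truth: GroundTruth


def mouse_symbol(i: int) -> str:
    return f"Stro{i:04d}"


def human_symbol(i: int) -> str:
    return mouse_symbol(i).upper()


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(sq.ALPHABET[b] for b in rng.integers(0, 4, size=n))


def generate_two_species_reference(config: SimulationConfig) -> ReferenceBundle:
    """Generate human and mouse transcript sets, the chip definition, and the
    ground truth of planted cross-hybridizing probes and true DE genes.

    Every mouse gene gets ``probes_per_set`` probes that are exact substrings
    of its transcript.  Planted cross-hybridizing probes have a contiguous
    window of recorded length >= ``min_planted_match`` copied into one human
    transcript; all other probes have no off-target contiguous match >=
    12 nt on either strand (rejection-sampled).
    """
    rng = np.random.default_rng([0, config.seed])
    n = config.n_genes_per_species
    plen = config.probe_length
    k = SPECIFICITY_KMER

    mouse_syms = [mouse_symbol(i) for i in range(n)]
    human_ids = [human_symbol(i) for i in range(n)]

    human = {hid: _random_seq(rng, config.human_transcript_nt) for hid in human_ids}
    forbidden: set[int] = set()
    for seq in human.values():
        forbidden |= sq.canonical_kmers(seq, k)

    # species-specific probes by rejection sampling
    probe_kmers: dict[str, set[int]] = {}
    chip: dict[str, list[tuple[str, str]]] = {}
    max_attempts = 200
    for sym in mouse_syms:
        probes: list[tuple[str, str]] = []
        for j in range(config.probes_per_set):
            pid = f"{sym}:p{j:02d}"
            for attempt in range(max_attempts):
                cand = _random_seq(rng, plen)
                kmers = sq.canonical_kmers(cand, k)
                if not (kmers & forbidden):
                    break
            else:
                raise InfeasibleSimulationError(
                    f"could not sample a species-specific probe for {pid} after "
                    f"{max_attempts} attempts; reduce probe density or sequence sizes"
                )
            probes.append((pid, cand))
            probe_kmers[pid] = kmers
            forbidden |= kmers
        chip[sym] = probes

    # mouse transcript: probes joined by random spacers (probes stay exact substrings)
    mouse: dict[str, str] = {}
    for sym in mouse_syms:
        parts = [_random_seq(rng, config.spacer_nt)]
        for _, pseq in chip[sym]:
            parts.append(pseq)
            parts.append(_random_seq(rng, config.spacer_nt))
        mouse[sym] = "".join(parts)

    # plant cross-hybridizing probes
    all_probe_ids = [pid for sym in mouse_syms for pid, _ in chip[sym]]
    probe_seq = {pid: pseq for sym in mouse_syms for pid, pseq in chip[sym]}
    all_probe_kmers: set[int] = set()
    for s in probe_kmers.values():
        all_probe_kmers |= s
    n_cross = int(round(config.frac_crosshyb_probes * len(all_probe_ids)))
    if config.crosshyb_gene_clustered:
        chosen: list[str] = []
        for g in rng.permutation(mouse_syms):
            if len(chosen) >= n_cross:
                break
            for pid, _ in chip[g]:
                if rng.random() < config.crosshyb_within_gene_rate:
                    chosen.append(pid)
                    if len(chosen) >= n_cross:
                        break
        planted_ids = sorted(chosen)
    else:
        planted_ids = sorted(rng.choice(all_probe_ids, size=n_cross, replace=False).tolist())
    occupied: dict[str, list[tuple[int, int]]] = {hid: [] for hid in human_ids}
    crosshyb: dict[str, int] = {}
    partner: dict[str, str] = {}

    for pid in planted_ids:
        pseq = probe_seq[pid]
        mlen = int(rng.integers(config.min_planted_match, plen + 1))
        start = int(rng.integers(0, plen - mlen + 1))
        window = pseq[start : start + mlen]
        if rng.random() < 0.5:
            window = sq.revcomp(window)
        own = probe_kmers[pid]
        placed = False
        max_plant_attempts = 1000
        for attempt in range(max_plant_attempts):
            hid = human_ids[int(rng.integers(0, len(human_ids)))]
            hseq = human[hid]
            if len(hseq) < mlen:
                continue
            pos = int(rng.integers(0, len(hseq) - mlen + 1))
            # the junction region around the candidate must not touch any
            # previously planted window (it would be overwritten or its k-mers
            # would collide during the junction check below)
            lo, hi = pos - JUNCTION_MARGIN, pos + mlen + JUNCTION_MARGIN
            if any(not (hi <= a or lo >= b) for a, b in occupied[hid]):
                continue
            new_seq = hseq[:pos] + window + hseq[pos + mlen :]
            region = new_seq[max(0, lo) : min(len(new_seq), hi)]
            new_kmers = sq.canonical_kmers(region, k)
            if (new_kmers - own) & all_probe_kmers:
                continue  # junction would give some other probe an off-target match
            human[hid] = new_seq
            occupied[hid].append((pos, pos + mlen))
            crosshyb[pid] = mlen
            partner[pid] = hid
            placed = True
            break
        if not placed:
            raise InfeasibleSimulationError(
                f"could not plant cross-hyb window for {pid} after "
                f"{max_plant_attempts} attempts; reduce frac_crosshyb_probes or "
                f"enlarge the off-target transcripts"
            )

    # true DE genes (stroma response in the osteoinductive xenografts)
    n_de = int(round(config.frac_de * n))
    de_syms = sorted(rng.choice(mouse_syms, size=n_de, replace=False).tolist())
    mean, sd = config.effect_size
    mags = np.maximum(config.min_effect, rng.normal(mean, sd, size=n_de))
    signs = np.where(rng.random(n_de) < config.frac_up, 1.0, -1.0)
    de_genes = {sym: float(s * m) for sym, s, m in zip(de_syms, signs, mags)}

    truth = GroundTruth(de_genes=de_genes, crosshyb_probes=crosshyb, crosshyb_partner=partner)
    return ReferenceBundle(mouse, human, ChipDefinition(chip), truth)


def build_design(config: SimulationConfig) -> pd.DataFrame:
    """Sample sheet: one row per array, with group, replicate and mixing ratio."""
    rows = []
    for group, n_rep in config.replicates.items():
        ratio = config.group_ratio(group)
        ratio_str = config.mixing_ratios.get(group, "0:1" if ratio == 0 else "1:9")
        for r in range(1, n_rep + 1):
            rows.append((f"{group}_{r}", group, group, r, ratio_str))
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "model", "replicate", "mixing_ratio"]
    ).set_index("sample_id")


def simulate_experiment(
    config: SimulationConfig,
    chipdef: ChipDefinition,
    truth: GroundTruth,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Probe-level intensities for the full sample design.

    The linear-scale intensity of probe ``p`` in sample ``s`` is the mouse
    transcript abundance of its gene (shifted by the true log2FC in the
    osteoinductive xenograft groups) plus, for planted cross-hybridizing
    probes, ``contamination_coef * ratio(s) * human_abundance(partner)``
    where ``ratio(s)`` is the sample's human:mouse RNA ratio.  Log-normal
    noise (additive Gaussian on the log2 scale) is applied on top.

    Returns (intensities: probes x samples, linear scale; design table).
    """
    rng = np.random.default_rng([1, config.seed])
    design = build_design(config)
    for group in design["group"].unique():
        config.group_ratio(group)  # raises KeyError on config/design mismatch

    probe_ids: list[str] = []
    gene_of_probe: list[str] = []
    for ps, probes in chipdef.probesets.items():
        for pid, _ in probes:
            probe_ids.append(pid)
            gene_of_probe.append(ps)
    genes = list(chipdef.probesets)
    gene_idx = {g: i for i, g in enumerate(genes)}

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=len(genes))
    partners = sorted(set(truth.crosshyb_partner.values()))
    human_abund = {
        hid: float(2.0 ** rng.normal(config.baseline_log2_mean, config.baseline_log2_sd))
        for hid in partners
    }

    lfc = np.zeros(len(genes))
    for sym, v in truth.de_genes.items():
        if sym in gene_idx:
            lfc[gene_idx[sym]] = v

    bleed = np.zeros(len(probe_ids))
    for i, pid in enumerate(probe_ids):
        if pid in truth.crosshyb_probes:
            bleed[i] = config.contamination_coef * human_abund[truth.crosshyb_partner[pid]]

    g_of_p = np.array([gene_idx[g] for g in gene_of_probe])
    values = np.empty((len(probe_ids), len(design)), dtype=np.float64)
    for j, (sample, row) in enumerate(design.iterrows()):
        ratio = config.group_ratio(row["group"])
        shift = lfc if row["group"] in DE_GROUPS else 0.0
        mouse_linear = 2.0 ** (baseline + shift)
        linear = mouse_linear[g_of_p] + ratio * bleed
        log2v = np.log2(linear)
        if config.noise_sd > 0:
            log2v = log2v + rng.normal(0.0, config.noise_sd, size=log2v.shape)
        values[:, j] = 2.0 ** log2v
    intensities = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                               columns=design.index)
    return intensities, design


# ---------------------------------------------------------------------------
# signature registry


@dataclass
class SignatureRegistry:
    """Synthetic 'published' signatures (human symbols) plus the analytically
    expected curation ledger (mouse symbols), recorded while planting."""

    signatures: dict[str, list[str]]  # name -> human symbols
    categories: dict[str, str]  # name -> curation category (niche sigs excluded)
    expected_removed: dict[str, list[str]]  # category -> mouse symbols removed at that stage
    expected_core: list[str]  # mouse symbols


def generate_signature_registry(
    truth: GroundTruth, config: SimulationConfig
) -> SignatureRegistry:
    """Emit category signatures with controlled overlaps against the true DE
    set, plus stem-cell-niche signatures, and the expected curation outcome.

    Overlap genes are drawn as disjoint subsets of the true DE set, one
    subset per category in curation order, so the expected ledger is exact
    set bookkeeping, independent of the curation implementation.
    """
    rng = np.random.default_rng([2, config.seed])
    de = sorted(truth.de_genes)
    n_mouse = config.n_genes_per_species
    non_de = sorted(set(mouse_symbol(i) for i in range(n_mouse)) - set(de))

    pool = list(de)
    expected_removed: dict[str, list[str]] = {}
    category_overlap_genes: dict[str, list[str]] = {}
    for cat in CATEGORY_ORDER:
        frac = config.category_overlap.get(cat, 0.0)
        n_cat = int(round(frac * len(de)))
        if n_cat > len(pool):
            raise InfeasibleSimulationError(
                f"requested overlap for category {cat} exceeds remaining DE genes"
            )
        chosen = sorted(rng.choice(pool, size=n_cat, replace=False).tolist()) if n_cat else []
        category_overlap_genes[cat] = chosen
        expected_removed[cat] = chosen
        pool = [g for g in pool if g not in set(chosen)]
    expected_core = pool

    signatures: dict[str, list[str]] = {}
    categories: dict[str, str] = {}
    for cat in CATEGORY_ORDER:
        names = CATEGORY_SIGNATURES[cat]
        shares: list[list[str]] = [[] for _ in names]
        for i, g in enumerate(category_overlap_genes[cat]):
            shares[i % len(names)].append(g)
        for name, share in zip(names, shares):
            filler = rng.choice(non_de, size=config.signature_filler, replace=False).tolist()
            members = sorted(set(share) | set(filler))
            signatures[name] = sorted({m.upper() for m in members})
            categories[name] = cat

    for name, (size, overlap) in config.niche_signatures.items():
        if overlap > len(de) or size - overlap > len(non_de):
            raise InfeasibleSimulationError(f"niche signature {name} infeasible")
        inside = rng.choice(de, size=overlap, replace=False).tolist()
        outside = rng.choice(non_de, size=size - overlap, replace=False).tolist()
        signatures[name] = sorted({m.upper() for m in inside + outside})

    truth.signature_memberships = {k: list(v) for k, v in signatures.items()}
    return SignatureRegistry(signatures, categories, expected_removed, expected_core)


# ---------------------------------------------------------------------------
# promoters


def generate_promoters(
    cluster_genes: list[str],
    background_genes: list[str],
    motif,
    rate_cluster: float,
    rate_background: float,
    window_nt: int = 2000,
    seed: int = 0,
) -> dict[str, str]:
    """Random promoter windows with the motif consensus planted per gene.

    Each gene gets one i.i.d. random sequence of ``window_nt``; the motif
    consensus is planted with probability ``rate_cluster`` (cluster genes) or
    ``rate_background`` (background genes), at a uniform position and strand.
    """
    if not 0 <= rate_cluster <= 1 or not 0 <= rate_background <= 1:
        raise ValueError("planting rates must be in [0, 1]")
    consensus = motif.consensus
    if len(consensus) > window_nt:
        raise ValueError("motif longer than promoter window")
    overlap = set(cluster_genes) & set(background_genes)
    if overlap:
        raise ValueError(f"cluster and background overlap: {sorted(overlap)[:3]}")
    rng = np.random.default_rng([3, seed])
    promoters: dict[str, str] = {}
    for genes, rate in ((cluster_genes, rate_cluster), (background_genes, rate_background)):
        for gene in genes:
            seq = _random_seq(rng, window_nt)
            if rng.random() < rate:
                site = consensus if rng.random() < 0.5 else sq.revcomp(consensus)
                pos = int(rng.integers(0, window_nt - len(site) + 1))
                seq = seq[:pos] + site + seq[pos + len(site) :]
            promoters[gene] = seq
    return promoters
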