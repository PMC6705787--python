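"""Seeded generator of multi-domain S1-like protein families with ground truth.

The generator emulates the statistical structure of the bacterial ribosomal
protein S1 family: each protein is a chain of 1-6 copies of a ~70-residue
S1-like repeat joined by short linkers, each copy independently diverged
from a single shared ancestral domain by a per-position substitution model.
Because evolution is substitution-only (no indels), expected pairwise
identity between two copies at divergences d_i and d_j has the closed form
``100 * [(1 - d_i)(1 - d_j) + d_i * d_j / 19]``, which the test suite checks
by Monte Carlo.

The per-index divergence vector defaults to a minimum at index 3, planting
the central domain as the most conserved — a recoverable signal for the
conservation locators. The phylum x domain-count profile defaults to the
empirical shares of the real S1 census (six-domain Proteobacteria dominate,
then four-domain Firmicutes/Actinobacteria, with one-, two-, three- and
five-domain architectures rare).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .records_io import AMINO_ACIDS, Dataset, ProteinRecord, write_dataset

#: Filter rules a contaminant record can be planted to violate.
CONTAMINATION_RULES = ("keyword", "gene", "candidate", "domain_presence", "extra_domain")

#: Default phylum profile: (phylum, domain_count, weight). Weights follow the
#: observed domain-count shares 0.8 / 0.6 / 1.9 / 33 / 1.1 / 62 percent, with
#: the four-domain share split between Actinobacteria and Firmicutes.
DEFAULT_PHYLUM_PROFILE: tuple[tuple[str, int, float], ...] = (
    ("Tenericutes", 1, 0.008),
    ("Actinobacteria", 2, 0.006),
    ("Cyanobacteria", 3, 0.019),
    ("Actinobacteria", 4, 0.165),
    ("Firmicutes", 4, 0.165),
    ("Deinococcus-Thermus", 5, 0.011),
    ("Proteobacteria", 6, 0.620),
)

#: Default per-index substitution probabilities; the minimum at index 3
#: plants the central domain as most conserved.
DEFAULT_DIVERGENCE: dict[int, float] = {1: 0.40, 2: 0.35, 3: 0.15, 4: 0.20, 5: 0.30, 6: 0.40}

_PASSING_NAME = "30S ribosomal protein S1"
_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated family; fully determines it given the seed."""

    seed: int = 0
    n_records: int = 200
    ancestral_length: int = 70
    linker_length: int = 10
    phylum_profile: tuple[tuple[str, int, float], ...] = DEFAULT_PHYLUM_PROFILE
    divergence: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_DIVERGENCE))
    contamination: dict[str, float] = field(default_factory=dict)
    contamination_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_records < 0:
            raise ValidationError("n_records must be non-negative")
        if self.ancestral_length < 1:
            raise ValidationError("ancestral_length must be >= 1")
        if self.linker_length < 0:
            raise ValidationError("linker_length must be >= 0")
        total = sum(w for _, _, w in self.phylum_profile)
        if not self.phylum_profile or total <= 0:
            raise ValidationError("phylum_profile must have positive total weight")
        if abs(total - 1.0) > 0.05:
            raise ValidationError(f"phylum_profile weights sum to {total:g}, expected ~1")
        for _, k, _ in self.phylum_profile:
            if k < 1:
                raise ValidationError("profile domain counts must be >= 1")
            if k not in self.divergence:
                missing = [i for i in range(1, k + 1) if i not in self.divergence]
                if missing:
                    raise ValidationError(f"divergence missing indices {missing}")
        for d in self.divergence.values():
            if not 0.0 <= d <= 1.0:
                raise ValidationError("divergence probabilities must lie in [0, 1]")
        for rules in (self.contamination, self.contamination_counts):
            unknown = set(rules) - set(CONTAMINATION_RULES)
            if unknown:
                raise ValidationError(f"unknown contamination rule(s) {sorted(unknown)}")
        for r in self.contamination.values():
            if not 0.0 <= r <= 1.0:
                raise ValidationError("contamination rates must lie in [0, 1]")

    @property
    def planted_index(self) -> int:
        """Index of the most conserved domain: argmin divergence, lowest on ties."""
        return min(sorted(self.divergence), key=lambda i: (self.divergence[i], i))


@dataclass
class FamilyTruth:
    """Generator ground truth for one simulated family."""

    ancestral_domain: str
    divergence: dict[int, float]
    planted_index: int
    realized_divergence: dict[str, tuple[float, ...]]  # accession -> per-domain
    intended_outcome: dict[str, str]  # accession -> "keep" or violated rule

    def to_json(self, path) -> None:
        payload = {
            "ancestral_domain": self.ancestral_domain,
            "divergence": {str(k): v for k, v in self.divergence.items()},
            "planted_index": self.planted_index,
            "realized_divergence": {
                acc: list(d) for acc, d in self.realized_divergence.items()
            },
            "intended_outcome": self.intended_outcome,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class SimulatedFamily:
    dataset: Dataset
    truth: FamilyTruth

    def write(self, fasta_path, meta_path, truth_path=None) -> None:
        write_dataset(self.dataset, fasta_path, meta_path)
        if truth_path is not None:
            self.truth.to_json(truth_path)


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_ancestral_domain(length: int, seed) -> str:
    """Uniform i.i.d. sequence over the 20 canonical residues."""
    if length < 1:
        raise ValidationError("ancestral domain length must be >= 1")
    rng = _as_rng(seed)
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def evolve_domain(ancestor: str, d: float, seed) -> str:
    """Substitute each site with probability *d* by one of the 19 other residues."""
    if not 0.0 <= d <= 1.0:
        raise ValidationError("substitution probability must lie in [0, 1]")
    rng = _as_rng(seed)
    seq = np.frombuffer(ancestor.encode(), dtype=np.uint8).copy()
    hit = np.where(rng.random(seq.size) < d)[0]
    for i in hit:
        # draw among the 19 residues other than the current one
        cur = int(np.where(_AA == seq[i])[0][0])
        repl = int(rng.integers(0, 19))
        if repl >= cur:
            repl += 1
        seq[i] = _AA[repl]
    return seq.tobytes().decode()


def assemble_protein(domains: list[str], linker_length: int, seed):
    """Concatenate domains with random linkers; return (sequence, boundaries).

    Boundaries are 1-based inclusive and slice back exactly the inputs;
    linker positions are never inside a boundary.
    """
    if not domains:
        raise ValidationError("assemble_protein requires at least one domain")
    rng = _as_rng(seed)
    parts: list[str] = []
    boundaries: list[tuple[int, int]] = []
    pos = 0
    for idx, dom in enumerate(domains):
        if idx > 0 and linker_length:
            parts.append(sample_ancestral_domain(linker_length, rng))
            pos += linker_length
        boundaries.append((pos + 1, pos + len(dom)))
        parts.append(dom)
        pos += len(dom)
    return "".join(parts), tuple(boundaries)


def _realized_divergence(ancestor: str, derived: str) -> float:
    diffs = sum(a != b for a, b in zip(ancestor, derived))
    return diffs / len(ancestor)


def simulate_dataset(cfg: SimulationConfig) -> SimulatedFamily:
    """Draw a full family: records, annotations, contaminants, ground truth.

    Contaminants violate exactly one filter rule each. Exact per-rule counts
    (``contamination_counts``) are assigned to a disjoint random subset of
    records; otherwise each record independently violates rule *r* with
    probability ``contamination[r]`` (first matching rule wins).
    """
    rng = np.random.default_rng(cfg.seed)
    ancestor = sample_ancestral_domain(cfg.ancestral_length, rng)

    phyla = [p for p, _, _ in cfg.phylum_profile]
    counts = [k for _, k, _ in cfg.phylum_profile]
    weights = np.array([w for _, _, w in cfg.phylum_profile], dtype=float)
    weights = weights / weights.sum()

    # assign contamination labels
    labels = ["keep"] * cfg.n_records
    if cfg.contamination_counts:
        total = sum(cfg.contamination_counts.values())
        if total > cfg.n_records:
            raise ValidationError("contamination_counts exceed n_records")
        chosen = rng.choice(cfg.n_records, size=total, replace=False)
        it = iter(chosen)
        for rule in CONTAMINATION_RULES:
            for _ in range(cfg.contamination_counts.get(rule, 0)):
                labels[int(next(it))] = rule
    else:
        for i in range(cfg.n_records):
            u = rng.random()
            acc = 0.0
            for rule in CONTAMINATION_RULES:
                acc += cfg.contamination.get(rule, 0.0)
                if u < acc:
                    labels[i] = rule
                    break

    records: list[ProteinRecord] = []
    realized: dict[str, tuple[float, ...]] = {}
    outcome: dict[str, str] = {}
    for i in range(cfg.n_records):
        accession = f"SYN{i:05d}"
        cell = int(rng.choice(len(phyla), p=weights))
        phylum, k = phyla[cell], counts[cell]
        domains = [evolve_domain(ancestor, cfg.divergence[idx], rng) for idx in range(1, k + 1)]
        sequence, boundaries = assemble_protein(domains, cfg.linker_length, rng)
        rule = labels[i]
        protein_name = _PASSING_NAME
        gene_name = "rpsA" if rng.random() < 0.8 else f"rpsA_{int(rng.integers(1, 4))}"
        lineage = ("Bacteria", phylum, f"{phylum} bacterium sp{i:05d}")
        has_extra = False
        if rule == "keyword":
            protein_name = "50S ribosomal protein L1"
        elif rule == "gene":
            gene_name = "rpsB"
        elif rule == "candidate":
            lineage = ("Bacteria", phylum, "Candidatus Pelagibacter", f"sp{i:05d}")
        elif rule == "domain_presence":
            boundaries = ()
        elif rule == "extra_domain":
            has_extra = True
        records.append(
            ProteinRecord(
                accession=accession,
                protein_name=protein_name,
                gene_name=gene_name,
                lineage=lineage,
                phylum=phylum,
                sequence=sequence,
                s1_boundaries=boundaries,
                has_extra_domains=has_extra,
            )
        )
        realized[accession] = tuple(_realized_divergence(ancestor, d) for d in domains)
        outcome[accession] = rule
    truth = FamilyTruth(
        ancestral_domain=ancestor,
        divergence=dict(cfg.divergence),
        planted_index=cfg.planted_index,
        realized_divergence=realized,
        intended_outcome=outcome,
    )
    ds = Dataset(records, provenance=f"simulated seed={cfg.seed} n={cfg.n_records}")
    return SimulatedFamily(ds, truth)


def expected_pair_identity(d_i: float, d_j: float) -> float:
    """Closed-form expected identity (%) between copies at divergences d_i, d_j.

    Both positions retain the ancestral residue with probability
    (1-d_i)(1-d_j); both substituted (prob d_i*d_j) coincide with
    probability 1/19 under the uniform replacement model.
    """
    return 100.0 * ((1.0 - d_i) * (1.0 - d_j) + d_i * d_j / 19.0)
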