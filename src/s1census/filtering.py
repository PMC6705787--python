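"""Record-selection rules that carve the analysis dataset out of raw records.

Five rules run in a fixed order, each a pure subset operation:

1. keyword  - protein name must contain one of the S1 family keywords;
2. gene     - gene must be rpsA or a numbered analog (rpsA_1, rpsA_2, ...);
3. candidate - taxa with provisional 'candidate'/'Candidatus' names are
   removed (no standing in nomenclature, no reliable phylum);
4. domain_presence - records with zero annotated S1 domains are removed;
5. extra_domain    - records carrying annotated non-S1 domains are removed.

The attrition funnel is recorded per rule in a :class:`FilterReport`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import ValidationError
from .records_io import Dataset

#: Protein-name keywords selecting the S1 family (matched lowercased,
#: as substrings).
KEYWORDS = (
    "30s ribosomal protein s1",
    "ribosomal protein s1",
    "30s ribosomal protein s1 (ec 1.17.1.2)",
    "30s ribosomal protein s1 (ribosomal protein s1)",
    "ribosomal protein s1 domain protein",
    "rna binding protein s1",
    "rna binding s1 domain protein",
    "s1 rna binding domain protein",
)

#: rpsA or a numbered analog, as a full token (rpsAB/rpsA2like are excluded).
GENE_PATTERN = re.compile(r"rpsa(_\d+)?\Z", re.IGNORECASE)

#: Stem matching both "candidate" and "Candidatus".
CANDIDATE_STEM = "candidat"

RULE_ORDER = ("keyword", "gene", "candidate", "domain_presence", "extra_domain")


@dataclass(frozen=True)
class FilterStep:
    rule: str
    n_in: int
    n_out: int
    dropped: tuple[str, ...]


@dataclass
class FilterReport:
    """Ordered per-rule attrition: counts in/out and dropped accessions."""

    steps: list[FilterStep]

    def __post_init__(self) -> None:
        prev_out = None
        for step in self.steps:
            if step.n_out != step.n_in - len(step.dropped):
                raise ValidationError(
                    f"rule {step.rule}: n_out {step.n_out} != n_in {step.n_in} "
                    f"- {len(step.dropped)} dropped"
                )
            if prev_out is not None and step.n_in != prev_out:
                raise ValidationError(
                    f"rule {step.rule}: n_in {step.n_in} != previous n_out {prev_out}"
                )
            prev_out = step.n_out

    @property
    def n_in(self) -> int:
        return self.steps[0].n_in if self.steps else 0

    @property
    def n_out(self) -> int:
        return self.steps[-1].n_out if self.steps else 0

    def dropped_by_rule(self) -> dict[str, tuple[str, ...]]:
        return {s.rule: s.dropped for s in self.steps}

    def to_tsv(self, path, dropped_path=None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("rule\tn_in\tn_out\tn_dropped\n")
            for s in self.steps:
                fh.write(f"{s.rule}\t{s.n_in}\t{s.n_out}\t{len(s.dropped)}\n")
        if dropped_path is not None:
            with open(dropped_path, "w", encoding="utf-8") as fh:
                for s in self.steps:
                    for acc in s.dropped:
                        fh.write(f"{s.rule}\t{acc}\n")


def _keyword_keep(rec) -> bool:
    name = rec.protein_name.lower()
    return any(kw in name for kw in KEYWORDS)


def _gene_keep(rec) -> bool:
    return GENE_PATTERN.fullmatch(rec.gene_name.strip()) is not None


def _candidate_keep(rec, stem: str = CANDIDATE_STEM) -> bool:
    fields = list(rec.lineage) + [rec.phylum]
    return not any(stem in f.lower() for f in fields)


def _domain_presence_keep(rec) -> bool:
    return rec.domain_count >= 1


def _extra_domain_keep(rec) -> bool:
    return not rec.has_extra_domains


def _accession_keep(rec) -> bool:
    # UniProt-annotated records carry six-character accessions.
    return len(rec.accession) == 6


def _apply(ds: Dataset, keep) -> tuple[Dataset, tuple[str, ...]]:
    kept = [rec for rec in ds if keep(rec)]
    dropped = tuple(rec.accession for rec in ds if not keep(rec))
    return Dataset(kept, ds.provenance), dropped


def keyword_filter(ds: Dataset) -> Dataset:
    """Keep records whose lowercased protein name contains an S1 keyword."""
    return _apply(ds, _keyword_keep)[0]


def gene_filter(ds: Dataset) -> Dataset:
    """Keep records encoded by rpsA or a numbered rpsA analog."""
    return _apply(ds, _gene_keep)[0]


def candidate_filter(ds: Dataset, stem: str = CANDIDATE_STEM) -> Dataset:
    """Drop records whose lineage or phylum names a candidate taxon."""
    return _apply(ds, lambda r: _candidate_keep(r, stem))[0]


def domain_presence_filter(ds: Dataset) -> Dataset:
    """Drop records with zero annotated S1 domains."""
    return _apply(ds, _domain_presence_keep)[0]


def extra_domain_filter(ds: Dataset) -> Dataset:
    """Drop records that carry annotated non-S1 domains."""
    return _apply(ds, _extra_domain_keep)[0]


def build_dataset(
    ds: Dataset,
    candidate_stem: str = CANDIDATE_STEM,
    strict_accession: bool = False,
) -> tuple[Dataset, FilterReport]:
    """Run the full funnel in order and return survivors plus the report.

    ``candidate_stem`` may be set to ``"candidate"`` to disable the
    Candidatus extension; ``strict_accession`` additionally restricts to
    six-character accessions (an annotated-record proxy, off by default).
    """
    rules = [
        ("keyword", _keyword_keep),
        ("gene", _gene_keep),
        ("candidate", lambda r: _candidate_keep(r, candidate_stem)),
        ("domain_presence", _domain_presence_keep),
        ("extra_domain", _extra_domain_keep),
    ]
    if strict_accession:
        rules.insert(0, ("accession", _accession_keep))
    steps = []
    current = ds
    for rule, keep in rules:
        n_in = len(current)
        current, dropped = _apply(current, keep)
        steps.append(FilterStep(rule, n_in, len(current), dropped))
    return current, FilterReport(steps)
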