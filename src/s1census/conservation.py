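"""Locating the conserved repeat: identity matrices and reference scans.

Three locators, computed per domain-count group, triangulate which repeat
of a multi-domain protein is most conserved:

* the diagonal of the inter-domain identity matrix - mean pairwise identity
  among all instances of domain *i* across records;
* the off-diagonal maximum - the pair of positions (i, j) whose instances
  are most alike;
* the reference scan - per record, the domain most similar to a fixed
  one-domain reference (e.g. the S1 domain of PNPase); its mode across the
  group.

All averages are unweighted over pairs; argmax ties break toward the lower
domain index so outputs are deterministic. For groups above a configurable
record cap, cell averages use a seeded random subsample of cross-record
pairs to bound the quadratic cost; the seed is recorded in the output.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .alignment import DEFAULT_SCHEME, ScoringScheme, encode_sequence, identity_encoded
from .errors import InsufficientDataError, ValidationError
from .records_io import Dataset, ProteinRecord

logger = logging.getLogger("s1census")

DEFAULT_PAIR_CAP = 500


@dataclass(frozen=True)
class DomainInstance:
    """One domain occurrence: which record, which position, which residues."""

    accession: str
    domain_index: int  # 1-based position along the chain
    subsequence: str


def extract_domains(rec: ProteinRecord) -> list[DomainInstance]:
    """Slice every annotated S1 domain out of the record, in chain order."""
    return [
        DomainInstance(rec.accession, idx, rec.domain_slice(start, end))
        for idx, (start, end) in enumerate(rec.s1_boundaries, start=1)
    ]


@dataclass
class IdentityMatrix:
    """Mean inter-domain identities for one domain-count group.

    ``values[i-1][j-1]`` is the mean identity (%) between domain position i
    of one record and position j of another; the diagonal averages over all
    cross-record pairs of the same position. ``n_pairs`` counts the aligned
    pairs behind each cell.
    """

    group: int
    values: np.ndarray
    n_pairs: np.ndarray
    n_records: int
    include_within_record: bool
    scheme: str
    subsample_seed: int | None = None

    def cell(self, i: int, j: int) -> float:
        return float(self.values[i - 1, j - 1])

    def diagonal_argmax(self) -> int:
        """Most conserved position by within-position identity (tie: lowest)."""
        return int(np.argmax(np.diag(self.values))) + 1

    def offdiagonal_argmax(self) -> tuple[int, int]:
        """(i, j), i < j, of the maximal off-diagonal cell (tie: lowest pair)."""
        k = self.group
        best, best_pair = -np.inf, (1, 2)
        for i in range(k):
            for j in range(i + 1, k):
                if self.values[i, j] > best:
                    best = self.values[i, j]
                    best_pair = (i + 1, j + 1)
        return best_pair

    def is_degenerate(self, tol: float = 1e-9) -> bool:
        return bool(np.ptp(self.values) <= tol)

    def to_tsv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            fh.write(f"# group={self.group} n_records={self.n_records} "
                     f"scheme={self.scheme} within_record={self.include_within_record} "
                     f"subsample_seed={self.subsample_seed}\n")
            fh.write("i\tj\tmean_identity\tn_pairs\n")
            for i in range(self.group):
                for j in range(self.group):
                    fh.write(f"{i + 1}\t{j + 1}\t{self.values[i, j]:.4f}\t"
                             f"{int(self.n_pairs[i, j])}\n")

    def to_json(self, path) -> None:
        payload = {
            "group": self.group,
            "n_records": self.n_records,
            "scheme": self.scheme,
            "include_within_record": self.include_within_record,
            "subsample_seed": self.subsample_seed,
            "values": self.values.tolist(),
            "n_pairs": self.n_pairs.astype(int).tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class RefScanResult:
    """Reference-scan outcome for one domain-count group."""

    reference_id: str
    group: int
    n_records: int
    best_index: dict[str, int]  # accession -> argmax domain position
    modal_index: int
    n_representatives: int
    mean_identity: float  # mean best identity over records at the modal index

    def to_rows(self):
        return [
            {
                "reference_id": self.reference_id,
                "group": self.group,
                "n_records": self.n_records,
                "modal_index": self.modal_index,
                "n_representatives": self.n_representatives,
                "mean_identity": round(self.mean_identity, 4),
            }
        ]


def write_refscan_tsv(results: list["RefScanResult"], path,
                      header_lines: list[str] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("reference_id\tgroup\tn_records\tmodal_index\t"
                 "n_representatives\tmean_identity\n")
        for res in results:
            for row in res.to_rows():
                fh.write("\t".join(str(row[c]) for c in (
                    "reference_id", "group", "n_records", "modal_index",
                    "n_representatives", "mean_identity")) + "\n")


def _group_records(ds: Dataset, k: int) -> list[ProteinRecord]:
    return [rec for rec in ds if rec.domain_count == k]


def _encoded_domains(records: list[ProteinRecord]) -> list[list[np.ndarray]]:
    return [
        [encode_sequence(d.subsequence, f"{rec.accession} domain") for d in extract_domains(rec)]
        for rec in records
    ]


def _cross_pairs(n: int, pair_cap: int, seed: int) -> tuple[np.ndarray, int | None]:
    """Unordered cross-record index pairs, subsampled when n exceeds the cap."""
    total = n * (n - 1) // 2
    pairs = np.array([(a, b) for a in range(n) for b in range(a + 1, n)], dtype=np.int64)
    if n <= pair_cap:
        return pairs, None
    target = pair_cap * (pair_cap - 1) // 2
    rng = np.random.default_rng(seed)
    idx = rng.choice(total, size=min(target, total), replace=False)
    logger.info("group of %d records: subsampling %d of %d pairs (seed=%d)",
                n, idx.size, total, seed)
    return pairs[np.sort(idx)], seed


def interdomain_identity_matrix(
    ds: Dataset,
    k: int,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    include_within_record: bool = True,
    pair_cap: int = DEFAULT_PAIR_CAP,
    subsample_seed: int = 0,
    denominator: str = "alignment",
) -> IdentityMatrix:
    """Mean identity between domain positions i and j over a k-domain group.

    Off-diagonal cells average identity(domain_i of a, domain_j of b) over
    both orientations of every cross-record pair and, by default, each
    record's own internal i-j pair. Diagonal cells average over cross-record
    pairs of the same position.
    """
    records = _group_records(ds, k)
    n = len(records)
    if n < 2:
        raise InsufficientDataError(
            f"identity matrix for k={k} needs >= 2 records, found {n}"
        )
    enc = _encoded_domains(records)
    sub = scheme.matrix()
    go, ge = scheme.gap_open, scheme.gap_extend
    sums = np.zeros((k, k))
    counts = np.zeros((k, k), dtype=np.int64)
    pairs, used_seed = _cross_pairs(n, pair_cap, subsample_seed)
    for a, b in pairs:
        da, db = enc[a], enc[b]
        for i in range(k):
            v = identity_encoded(da[i], db[i], sub, go, ge, denominator)
            sums[i, i] += v
            counts[i, i] += 1
            for j in range(i + 1, k):
                v = identity_encoded(da[i], db[j], sub, go, ge, denominator)
                w = identity_encoded(db[i], da[j], sub, go, ge, denominator)
                sums[i, j] += v + w
                counts[i, j] += 2
    if include_within_record:
        for da in enc:
            for i in range(k):
                for j in range(i + 1, k):
                    v = identity_encoded(da[i], da[j], sub, go, ge, denominator)
                    sums[i, j] += v
                    counts[i, j] += 1
    values = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    # mirror the upper triangle
    for i in range(k):
        for j in range(i + 1, k):
            values[j, i] = values[i, j]
            counts[j, i] = counts[i, j]
    return IdentityMatrix(
        group=k,
        values=values,
        n_pairs=counts,
        n_records=n,
        include_within_record=include_within_record,
        scheme=scheme.describe(),
        subsample_seed=used_seed,
    )


def within_position_identity(
    ds: Dataset,
    k: int,
    i: int,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    pair_cap: int = DEFAULT_PAIR_CAP,
    subsample_seed: int = 0,
    denominator: str = "alignment",
) -> float:
    """Mean pairwise identity among domain-i instances across distinct records."""
    records = _group_records(ds, k)
    n = len(records)
    if n < 2:
        raise InsufficientDataError(
            f"within-position identity for k={k} needs >= 2 records, found {n}"
        )
    if not 1 <= i <= k:
        raise ValidationError(f"domain index {i} outside 1..{k}")
    enc = [row[i - 1] for row in _encoded_domains(records)]
    sub = scheme.matrix()
    pairs, _ = _cross_pairs(n, pair_cap, subsample_seed)
    vals = [
        identity_encoded(enc[a], enc[b], sub, scheme.gap_open, scheme.gap_extend,
                         denominator)
        for a, b in pairs
    ]
    return float(np.mean(vals))


def reference_scan(
    ds: Dataset,
    reference: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    reference_id: str = "reference",
    denominator: str = "alignment",
) -> list[RefScanResult]:
    """Scan every record's domains against a one-domain reference.

    Per record, ``best_index`` is the domain position with maximal identity
    to the reference (ties to the lowest index). Per group, the modal best
    index, its frequency, and the mean identity over the records voting for
    it summarise where the reference-like repeat sits.
    """
    if not reference:
        raise ValidationError("reference sequence must be non-empty")
    ref = encode_sequence(reference, "reference")
    sub = scheme.matrix()
    go, ge = scheme.gap_open, scheme.gap_extend
    groups: dict[int, list[ProteinRecord]] = {}
    for rec in ds:
        if rec.domain_count >= 1:
            groups.setdefault(rec.domain_count, []).append(rec)
    results = []
    for k in sorted(groups):
        records = groups[k]
        if not records:
            logger.info("reference scan: empty group k=%d skipped", k)
            continue
        best_index: dict[str, int] = {}
        best_value: dict[str, float] = {}
        for rec, row in zip(records, _encoded_domains(records)):
            ids = np.array([
                identity_encoded(dom, ref, sub, go, ge, denominator) for dom in row
            ])
            idx = int(np.argmax(ids))  # first maximum -> lowest index on ties
            best_index[rec.accession] = idx + 1
            best_value[rec.accession] = float(ids[idx])
        votes = Counter(best_index.values())
        top = max(votes.values())
        modal = min(i for i, c in votes.items() if c == top)
        reps = [acc for acc, i in best_index.items() if i == modal]
        mean_id = float(np.mean([best_value[acc] for acc in reps]))
        results.append(
            RefScanResult(
                reference_id=reference_id,
                group=k,
                n_records=len(records),
                best_index=best_index,
                modal_index=modal,
                n_representatives=len(reps),
                mean_identity=mean_id,
            )
        )
    return results


@dataclass
class ConservationSummary:
    """Agreement report of the three conserved-repeat locators for one group."""

    group: int
    diagonal_argmax: int
    offdiagonal_argmax: tuple[int, int]
    reference_modal: dict[str, int] = field(default_factory=dict)
    degenerate: bool = False
    agreement: bool = False
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "diagonal_argmax": self.diagonal_argmax,
            "offdiagonal_argmax": list(self.offdiagonal_argmax),
            "reference_modal": self.reference_modal,
            "degenerate": self.degenerate,
            "agreement": self.agreement,
            "note": self.note,
        }


def conserved_domain_summary(
    matrix: IdentityMatrix, scans: list[RefScanResult]
) -> ConservationSummary:
    """Cross-check the three locators for one group and flag (dis)agreement."""
    for scan in scans:
        if scan.group != matrix.group:
            raise ValidationError(
                f"reference scan group {scan.group} != matrix group {matrix.group}"
            )
    diag = matrix.diagonal_argmax()
    pair = matrix.offdiagonal_argmax()
    ref_modal = {s.reference_id: s.modal_index for s in scans}
    degenerate = matrix.is_degenerate()
    modal_values = set(ref_modal.values())
    agreement = (
        diag in pair
        and (not modal_values or modal_values <= set(pair) | {diag})
    )
    note = "degenerate (uniform identity)" if degenerate else (
        "all locators agree" if agreement else "locators disagree"
    )
    return ConservationSummary(
        group=matrix.group,
        diagonal_argmax=diag,
        offdiagonal_argmax=pair,
        reference_modal=ref_modal,
        degenerate=degenerate,
        agreement=agreement,
        note=note,
    )
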