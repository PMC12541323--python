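"""Curation of the domain-swap variant library.

The SH2 library in this pipeline is assembled in stages: a large candidate
pool of aligned domains is deduplicated, split into identity bands relative
to the human reference (close "Tec-like" domains at >=40% identity, distant
domains at 25-40%), per-paralog subsets are chosen by progressive identity
ranking, and point-substitution controls are added at the phosphotyrosine-
binding arginine (position 307 in human BTK numbering): an R->K control set
for domains above 60% identity, and a premature-stop control set for domains
above 95% identity.  The second (kinase-helix) library is curated by simple
deduplication plus the human paralog sequences.  Everything ends up in a
:class:`LibraryManifest`, a flat auditable table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .seq_core import (
    AlignedSet,
    ProteinSequence,
    ResidueMap,
    hamming_distance,
    pairwise_identity,
)

log = logging.getLogger(__name__)

ORIGIN_TAGS = ("extant", "ancestral", "control_RK", "control_stop", "wt_synonym")


@dataclass(frozen=True)
class DomainRecord:
    """One candidate domain sequence with provenance.

    ``aligned`` may be empty for records that only exist ungapped (the
    kinase-helix library is built from unaligned sequences).
    """

    id: str
    aligned: str
    ungapped: str
    origin: str = "extant"
    source_protein: str = ""
    species: str = ""
    identity_to_ref: float = float("nan")
    parent_id: str = ""

    def __post_init__(self) -> None:
        if self.origin not in ORIGIN_TAGS:
            raise ValueError(f"unknown origin tag {self.origin!r}")
        if self.origin in ("control_RK", "control_stop") and not self.parent_id:
            raise ValueError(f"control record {self.id!r} must reference a parent id")
        if "-" in self.ungapped:
            raise ValueError("ungapped sequence contains a gap character")

    def as_protein(self) -> ProteinSequence:
        return ProteinSequence(self.id, self.aligned or self.ungapped)


def from_alignment(msa: AlignedSet, origin: str = "extant") -> list[DomainRecord]:
    return [
        DomainRecord(
            id=r.id,
            aligned=r.residues,
            ungapped=r.residues.replace("-", ""),
            origin=origin,
        )
        for r in msa
    ]


@dataclass
class LibraryManifest:
    """The ordered, audited set of protein variants forming one library."""

    records: list[DomainRecord]
    ref_id: str = ""
    band_thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValueError(f"duplicate ids in manifest: {sorted(dup)[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def counts_by_origin(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.origin] = out.get(r.origin, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "origin": [r.origin for r in self.records],
                "identity_to_ref": [r.identity_to_ref for r in self.records],
                "parent_id": [r.parent_id for r in self.records],
                "sequence": [r.ungapped for r in self.records],
                "aligned": [r.aligned for r in self.records],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LibraryManifest":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        records = [
            DomainRecord(
                id=str(row.id),
                aligned=str(row.aligned),
                ungapped=str(row.sequence),
                origin=str(row.origin),
                identity_to_ref=float(row.identity_to_ref)
                if str(row.identity_to_ref) not in ("", "nan")
                else float("nan"),
                parent_id=str(row.parent_id),
            )
            for row in df.itertuples()
        ]
        return cls(records)


# ---------------------------------------------------------------------------
# Curation operations


def deduplicate(domains: Sequence[DomainRecord]) -> list[DomainRecord]:
    """Drop exact duplicates (by ungapped sequence), keeping first occurrences."""
    seen: set[str] = set()
    out = []
    for d in domains:
        if d.ungapped not in seen:
            seen.add(d.ungapped)
            out.append(d)
    return out


def band_filter(
    domains: Sequence[DomainRecord],
    ref: ProteinSequence,
    lo: float,
    hi: float,
    inclusive_hi: bool = False,
    denominator: str = "nongap_union",
) -> list[DomainRecord]:
    """Keep domains whose aligned identity to ``ref`` falls in [lo, hi) (or [lo, hi]).

    The low bound is always inclusive; the high bound is exclusive by default
    so adjacent bands partition the identity range without overlap.
    Returned records carry their computed ``identity_to_ref``.
    """
    if not lo < hi:
        raise ValueError("band requires lo < hi")
    out = []
    for d in domains:
        ident = pairwise_identity(
            d.as_protein(), ref, aligned=bool(d.aligned), denominator=denominator
        )
        if ident >= lo and (ident <= hi if inclusive_hi else ident < hi):
            out.append(replace(d, identity_to_ref=ident))
    return out


def progressive_select(
    candidates: Sequence[DomainRecord],
    ref: ProteinSequence,
    k: int = 14,
    denominator: str = "nongap_union",
) -> list[DomainRecord]:
    """Pick ``k`` domains spanning the identity range to ``ref`` at even ranks.

    Candidates at Hamming distance exactly 1 from the reference (over shared
    non-gap columns) are excluded first: such near-duplicates carry almost no
    information beyond the reference itself.  Survivors are sorted by
    identity ascending (ties broken by id for determinism) and ``k`` are
    taken by stepping through the ranked list at a stride of ``n // k``
    starting from the least identical survivor, so the picks climb evenly
    through the identity range.  If fewer than ``k`` survive, all are
    returned with a warning.
    """
    survivors = []
    for d in candidates:
        if d.aligned and hamming_distance(d.as_protein(), ref) == 1:
            continue
        ident = pairwise_identity(
            d.as_protein(), ref, aligned=bool(d.aligned), denominator=denominator
        )
        survivors.append(replace(d, identity_to_ref=ident))
    if not survivors:
        raise ValueError("no candidates survive the single-mismatch exclusion")
    survivors.sort(key=lambda d: (d.identity_to_ref, d.id))
    n = len(survivors)
    if n <= k:
        if n < k:
            log.warning("progressive_select: only %d survivors for k=%d", n, k)
        return survivors
    stride = n // k
    ranks = [i * stride for i in range(k)]
    return [survivors[r] for r in ranks]


def _substitute_at_307(
    domains: Sequence[DomainRecord],
    ref: ProteinSequence,
    residue_map: ResidueMap,
    threshold: float,
    target_residue: int,
    new_aa: str,
    tag: str,
    denominator: str,
) -> list[DomainRecord]:
    column = residue_map.residue_to_column(target_residue)
    if column is None:
        raise ValueError(f"reference residue {target_residue} is not mapped")
    out = []
    for d in domains:
        ident = (
            d.identity_to_ref
            if d.identity_to_ref == d.identity_to_ref  # not NaN
            else pairwise_identity(
                d.as_protein(), ref, aligned=True, denominator=denominator
            )
        )
        if ident <= threshold:
            continue
        if not d.aligned or column >= len(d.aligned):
            log.warning("%s: column for residue %d out of range; skipped", d.id, target_residue)
            continue
        aa = d.aligned[column]
        if aa == "-":
            log.warning("%s: gap at residue %d column; skipped", d.id, target_residue)
            continue
        if aa != "R":
            log.warning(
                "%s: residue at %d-equivalent column is %s, not R; skipped",
                d.id,
                target_residue,
                aa,
            )
            continue
        mutated = d.aligned[:column] + new_aa + d.aligned[column + 1 :]
        suffix = "K" if new_aa == "K" else "X"
        out.append(
            DomainRecord(
                id=f"{d.id}_R{target_residue}{suffix}",
                aligned=mutated,
                ungapped=mutated.replace("-", ""),
                origin=tag,
                identity_to_ref=ident,
                parent_id=d.id,
            )
        )
    return out


def make_rk_controls(
    domains: Sequence[DomainRecord],
    ref: ProteinSequence,
    residue_map: ResidueMap,
    threshold: float = 60.0,
    target_residue: int = 307,
    denominator: str = "nongap_union",
) -> list[DomainRecord]:
    """Arginine-to-lysine controls at the phosphotyrosine-binding position.

    Emitted for every domain with identity to ``ref`` strictly above
    ``threshold`` that carries an Arg at the column mapped to
    ``target_residue``; domains with a different residue there (or a gap)
    are skipped with a warning, never mutated silently.
    """
    return _substitute_at_307(
        domains, ref, residue_map, threshold, target_residue, "K", "control_RK", denominator
    )


def make_stop_controls(
    domains: Sequence[DomainRecord],
    ref: ProteinSequence,
    residue_map: ResidueMap,
    threshold: float = 95.0,
    target_residue: int = 307,
    denominator: str = "nongap_union",
) -> list[DomainRecord]:
    """Premature-stop controls: same rule as R->K but substituting ``*``."""
    return _substitute_at_307(
        domains, ref, residue_map, threshold, target_residue, "*", "control_stop", denominator
    )


def drop_by_id(
    domains: Sequence[DomainRecord], excluded_ids: Iterable[str]
) -> list[DomainRecord]:
    """Declarative manifest filter: drop listed lineage/accession ids."""
    excl = set(excluded_ids)
    return [d for d in domains if d.id not in excl]


def drop_long_domains(
    domains: Sequence[DomainRecord], max_length: int = 88
) -> list[DomainRecord]:
    """Declarative manifest filter: drop domains with ungapped length > max."""
    return [d for d in domains if len(d.ungapped) <= max_length]


def assemble_manifest(
    base: Sequence[DomainRecord],
    rk_controls: Sequence[DomainRecord] = (),
    stop_controls: Sequence[DomainRecord] = (),
    wt_synonyms: Sequence[DomainRecord] = (),
    ref_id: str = "",
    band_thresholds: dict | None = None,
) -> LibraryManifest:
    """Concatenate the library parts into one manifest; duplicate ids are an error."""
    records = list(base) + list(rk_controls) + list(stop_controls) + list(wt_synonyms)
    return LibraryManifest(
        records=records,
        ref_id=ref_id,
        band_thresholds=band_thresholds or {},
    )
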