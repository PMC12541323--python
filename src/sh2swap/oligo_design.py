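"""Reverse translation and synthesis design of the variant oligo pool.

Protein variants become synthesizable DNA by a codon-preserving rule: where a
variant residue matches the reference (human BTK) at the aligned position,
the reference codon is reused verbatim; everywhere else a synonymous codon is
drawn uniformly at random.  Draws that create a BsaI recognition site
(GGTCTC, or GAGACC on the opposite strand) inside the variable region are
locally resampled — the site must appear only in the fixed cloning handles,
where it drives Golden-Gate assembly.  Each protein is realized as several
synonymous nucleotide sequences (default four) so that wild-type-like
normalization has internal replication, and the finished oligo is padded
with a constant filler to a uniform synthesis length of 300 nt.

Randomness is fully deterministic: the pool-level seed is combined with a
stable hash of the variant id and the synonym index, so the draw for one
variant never depends on the order in which variants are processed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .seq_core import NucleotideSequence, translate_cds

LEFT_HANDLE = "CAGGCATGGTCTCATGAG"
RIGHT_HANDLE = "CAGCAGAGACCCGATTGG"
BSAI = "GGTCTC"
BSAI_RC = "GAGACC"
DEFAULT_FORBIDDEN = (BSAI, BSAI_RC)
TARGET_LENGTH = 300

#: Barcodes identifying the SH2 background carried by a kinase-helix variant,
#: placed immediately after the stop codon.
BACKGROUND_BARCODES: dict[str, tuple[str, str]] = {
    "BTK": ("TTC", "CCT"),
    "BMX-H": ("GGA", "AAG"),
}


def _build_codon_sets() -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for codon, aa in standard_dna_table.forward_table.items():
        sets.setdefault(aa, []).append(codon)
    sets["*"] = sorted(standard_dna_table.stop_codons)
    return {aa: sorted(codons) for aa, codons in sets.items()}


#: amino acid -> sorted synonymous codons (includes '*' -> the 3 stops)
CODON_SETS = _build_codon_sets()


def default_filler() -> str:
    """The packaged constant padding sequence (synthetic stand-in, BsaI-free)."""
    text = (resources.files("sh2swap.data") / "filler_synthetic.fasta").read_text()
    return "".join(l.strip() for l in text.splitlines() if not l.startswith(">"))


def _variant_rng(seed: int, variant_id: str, stream: int) -> np.random.Generator:
    tag = zlib.crc32(variant_id.encode()) & 0x7FFFFFFF
    return np.random.default_rng([seed & 0x7FFFFFFF, tag, stream])


def _reverse_complement(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def contains_forbidden(seq: str, forbidden=DEFAULT_FORBIDDEN) -> bool:
    return any(m in seq for m in forbidden)


def reverse_translate(
    protein: str,
    ref_protein: str,
    ref_cds: str,
    rng: np.random.Generator | int,
    forbidden=DEFAULT_FORBIDDEN,
    max_attempts: int = 100,
) -> str:
    """Codon-preserving reverse translation of ``protein`` against a reference.

    ``protein`` and ``ref_protein`` must be the same length; they may carry
    gap characters from a shared alignment (gap columns emit no codon).
    ``ref_cds`` must translate to the ungapped ``ref_protein``.  Positions
    where the variant residue equals the reference residue reuse the
    reference codon; all other positions draw a uniform synonymous codon.
    Draws producing a forbidden motif are resampled locally, at most
    ``max_attempts`` rounds per offending window; a motif forced entirely by
    reference-fixed codons is an error.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if len(protein) != len(ref_protein):
        raise ValueError(
            f"variant and reference must be position-aligned "
            f"({len(protein)} != {len(ref_protein)})"
        )
    ungapped_ref = ref_protein.replace("-", "")
    if translate_cds(ref_cds) != ungapped_ref:
        raise ValueError("ref_cds does not translate to ref_protein")

    ref_codons = [ref_cds[3 * i : 3 * i + 3] for i in range(len(ungapped_ref))]
    codons: list[str] = []
    fixed: list[bool] = []  # True where the reference codon was reused
    ref_pos = 0
    for aa, ref_aa in zip(protein, ref_protein):
        if ref_aa != "-":
            ref_codon = ref_codons[ref_pos]
            ref_pos += 1
        else:
            ref_codon = None
        if aa == "-":
            continue
        if ref_codon is not None and aa == ref_aa:
            codons.append(ref_codon)
            fixed.append(True)
        else:
            options = CODON_SETS[aa]
            codons.append(options[rng.integers(len(options))])
            fixed.append(False)

    cds = "".join(codons)
    for _ in range(max_attempts):
        window = _first_forbidden_window(cds, forbidden)
        if window is None:
            return cds
        start, end = window
        free = [
            i for i in range(start // 3, (end - 1) // 3 + 1)
            if i < len(codons) and not fixed[i] and len(CODON_SETS[_codon_aa(codons[i])]) > 1
        ]
        if not free:
            raise ValueError(
                f"forbidden motif at CDS positions {start}-{end} is forced by "
                "reference-fixed codons and cannot be resampled"
            )
        for i in free:
            options = CODON_SETS[_codon_aa(codons[i])]
            codons[i] = options[rng.integers(len(options))]
        cds = "".join(codons)
    raise ValueError("could not remove forbidden motif within attempt budget")


def _codon_aa(codon: str) -> str:
    return standard_dna_table.forward_table.get(codon, "*")


def _first_forbidden_window(cds: str, forbidden) -> tuple[int, int] | None:
    best = None
    for motif in forbidden:
        idx = cds.find(motif)
        if idx >= 0 and (best is None or idx < best[0]):
            best = (idx, idx + len(motif))
    return best


def make_synonymous_variants(
    protein: str,
    ref_protein: str,
    ref_cds: str,
    variant_id: str,
    n: int = 4,
    seed: int = 0,
    forbidden=DEFAULT_FORBIDDEN,
) -> list[str]:
    """``n`` independent codon realizations of one protein variant.

    Positions identical to the reference are invariant across the draws (the
    reference codon is always reused), so the realizations differ only where
    the protein differs from the reference.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return [
        reverse_translate(
            protein, ref_protein, ref_cds,
            _variant_rng(seed, variant_id, stream), forbidden,
        )
        for stream in range(n)
    ]


def wt_codon_variants(
    ref_cds: str,
    n_variants: int,
    n_positions: int = 5,
    seed: int = 0,
    forbidden=DEFAULT_FORBIDDEN,
    max_retries: int = 1000,
) -> list[str]:
    """Synonymous recodings of the wild-type CDS for use as normalization anchors.

    Each variant substitutes a synonymous codon at exactly ``n_positions``
    randomly chosen codon positions (only positions with at least two
    synonymous codons are eligible).  All variants are distinct from the
    reference and from each other, and remain free of forbidden motifs.
    """
    n_codons = len(ref_cds) // 3
    ref_codons = [ref_cds[3 * i : 3 * i + 3] for i in range(n_codons)]
    eligible = [
        i for i, c in enumerate(ref_codons) if len(CODON_SETS[_codon_aa(c)]) > 1
    ]
    if len(eligible) < n_positions:
        raise ValueError(
            f"only {len(eligible)} codons have synonyms; need {n_positions}"
        )
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x5757])
    out: list[str] = []
    seen = {ref_cds}
    for _ in range(max_retries):
        if len(out) == n_variants:
            break
        pos = rng.choice(len(eligible), size=n_positions, replace=False)
        codons = list(ref_codons)
        for p in pos:
            i = eligible[p]
            alts = [c for c in CODON_SETS[_codon_aa(codons[i])] if c != codons[i]]
            codons[i] = alts[rng.integers(len(alts))]
        cds = "".join(codons)
        if cds in seen or contains_forbidden(cds, forbidden):
            continue
        seen.add(cds)
        out.append(cds)
    if len(out) < n_variants:
        raise ValueError(
            f"could not generate {n_variants} distinct wild-type codon variants"
        )
    return out


@dataclass(frozen=True)
class OligoRecord:
    """One fully assembled synthesis oligo."""

    variant_id: str
    synonym_index: int
    cds: str
    barcode: str = ""
    background: str = ""
    left_handle: str = LEFT_HANDLE
    right_handle: str = RIGHT_HANDLE
    oligo: str = field(default="")

    @property
    def variable_region(self) -> str:
        return self.cds


def finalize_oligo(
    cds: str,
    variant_id: str,
    synonym_index: int = 1,
    barcode: str = "",
    background: str = "",
    left_handle: str = LEFT_HANDLE,
    right_handle: str = RIGHT_HANDLE,
    filler: str | None = None,
    target_len: int = TARGET_LENGTH,
) -> OligoRecord:
    """Assemble handle + CDS (+ barcode) + handle and pad to ``target_len``.

    The filler is a constant sequence taken from offset 0; a core longer than
    ``target_len`` is an error.  Layout: left handle, variable region, 3-nt
    barcode (kinase-helix library only), right handle, filler.
    """
    if filler is None:
        filler = default_filler()
    core = left_handle + cds + barcode + right_handle
    pad = target_len - len(core)
    if pad < 0:
        raise ValueError(
            f"assembled core is {len(core)} nt, exceeding target {target_len}"
        )
    if pad > len(filler):
        raise ValueError("filler too short for required padding")
    oligo = core + filler[:pad]
    return OligoRecord(
        variant_id=variant_id,
        synonym_index=synonym_index,
        cds=cds,
        barcode=barcode,
        background=background,
        left_handle=left_handle,
        right_handle=right_handle,
        oligo=oligo,
    )


def assign_barcodes(
    records: list[OligoRecord],
    barcode_map: dict[str, tuple[str, str]] | None = None,
) -> list[OligoRecord]:
    """Attach background-identifying barcodes to kinase-helix oligos.

    Each record must carry a known ``background`` label.  The two barcodes of
    a background are alternated deterministically over that background's
    records, mirroring the two-primer cloning scheme.  The barcode slot of
    the returned records is filled and the oligo is re-assembled.
    """
    if barcode_map is None:
        barcode_map = BACKGROUND_BARCODES
    counters: dict[str, int] = {}
    out = []
    for rec in records:
        if rec.background not in barcode_map:
            raise ValueError(f"unknown background label {rec.background!r}")
        i = counters.get(rec.background, 0)
        counters[rec.background] = i + 1
        barcode = barcode_map[rec.background][i % 2]
        out.append(
            finalize_oligo(
                rec.cds,
                rec.variant_id,
                rec.synonym_index,
                barcode=barcode,
                background=rec.background,
                left_handle=rec.left_handle,
                right_handle=rec.right_handle,
                target_len=len(rec.oligo) if rec.oligo else TARGET_LENGTH,
            )
        )
    return out


def demux_barcode(
    barcode: str, barcode_map: dict[str, tuple[str, str]] | None = None
) -> str | None:
    """Invert the barcode map; unknown barcodes return ``None`` (no correction)."""
    if barcode_map is None:
        barcode_map = BACKGROUND_BARCODES
    for background, codes in barcode_map.items():
        if barcode in codes:
            return background
    return None


def design_pool(
    proteins: list[tuple[str, str]],  # (variant_id, aligned protein)
    ref_protein: str,
    ref_cds: str,
    seed: int,
    n_synonyms: int = 4,
    filler: str | None = None,
    target_len: int = TARGET_LENGTH,
) -> list[OligoRecord]:
    """Design the full oligo pool: ``n_synonyms`` realizations per protein."""
    if filler is None:
        filler = default_filler()
    pool = []
    for variant_id, protein in proteins:
        for syn_idx, cds in enumerate(
            make_synonymous_variants(
                protein, ref_protein, ref_cds, variant_id, n=n_synonyms, seed=seed
            ),
            start=1,
        ):
            pool.append(
                finalize_oligo(
                    cds, variant_id, syn_idx, filler=filler, target_len=target_len
                )
            )
    return pool


def pool_to_fasta(pool: list[OligoRecord], path: str | Path) -> None:
    from .seq_core import write_fasta

    write_fasta(
        [
            NucleotideSequence(f"{r.variant_id}|syn{r.synonym_index}", r.oligo)
            for r in pool
        ],
        path,
    )
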