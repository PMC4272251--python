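"""Deterministic synthetic stand-in for the rCRS mitochondrial reference.

The canonical human mtDNA reference (rCRS, NC_012920.1) cannot be shipped
here, so the packaged reference is a SYNTHETIC sequence that reproduces the
structural features the pipeline relies on, on the canonical coordinate
system:

* length exactly 16,569 bases, circular coordinates;
* the historic placeholder base 'N' at position 3107;
* the canonical gene map (gene names, strands and feature classes from the
  public NC_012920.1 annotation, with overlapping gene boundaries trimmed so
  every gene owns a single reading frame);
* stop-free reading frames in every protein-coding gene, ATG/ATA starts;
* the poly-C tract at m.16184-16193 (cytosine run interrupted by T at 16189);
* documented bases at positions used as worked examples: m.250 T in the
  noncoding control region, m.2905 A in MTRNR2, m.5009 A as the third
  position of a leucine codon in MTND2 (so A>G there is synonymous).

Everything else is filled pseudo-randomly from a fixed seed, so the packaged
FASTA can be regenerated bit-for-bit with :func:`build_synthetic_rcrs`.
"""

from __future__ import annotations

import random

from .refmodel import (
    GenomeRegion,
    MT_CODON_TABLE,
    ReferenceModel,
    reverse_complement,
)

RCRS_LENGTH = 16569
_BUILD_SEED = 16569  # fixed: the packaged FASTA is this generator's output

#: (start, end, label, class, strand) — canonical NC_012920.1 gene map with
#: overlaps trimmed (MTTQ, MTTY, MTATP8, MTATP6, MTND4L end/start adjusted).
GENE_TABLE: list[tuple[int, int, str, str, str]] = [
    (577, 647, "MTTF", "tRNA", "+"),
    (648, 1601, "MTRNR1", "rRNA", "+"),
    (1602, 1670, "MTTV", "tRNA", "+"),
    (1671, 3229, "MTRNR2", "rRNA", "+"),
    (3230, 3304, "MTTL1", "tRNA", "+"),
    (3307, 4262, "MTND1", "protein-coding", "+"),
    (4263, 4331, "MTTI", "tRNA", "+"),
    (4332, 4400, "MTTQ", "tRNA", "-"),
    (4402, 4469, "MTTM", "tRNA", "+"),
    (4470, 5511, "MTND2", "protein-coding", "+"),
    (5512, 5579, "MTTW", "tRNA", "+"),
    (5587, 5655, "MTTA", "tRNA", "-"),
    (5657, 5729, "MTTN", "tRNA", "-"),
    (5761, 5826, "MTTC", "tRNA", "-"),
    (5827, 5891, "MTTY", "tRNA", "-"),
    (5904, 7445, "MTCO1", "protein-coding", "+"),
    (7446, 7514, "MTTS1", "tRNA", "-"),
    (7518, 7585, "MTTD", "tRNA", "+"),
    (7586, 8269, "MTCO2", "protein-coding", "+"),
    (8295, 8364, "MTTK", "tRNA", "+"),
    (8366, 8526, "MTATP8", "protein-coding", "+"),
    (8527, 9206, "MTATP6", "protein-coding", "+"),
    (9207, 9990, "MTCO3", "protein-coding", "+"),
    (9991, 10058, "MTTG", "tRNA", "+"),
    (10059, 10404, "MTND3", "protein-coding", "+"),
    (10405, 10469, "MTTR", "tRNA", "+"),
    (10470, 10759, "MTND4L", "protein-coding", "+"),
    (10760, 12137, "MTND4", "protein-coding", "+"),
    (12138, 12206, "MTTH", "tRNA", "+"),
    (12207, 12265, "MTTS2", "tRNA", "+"),
    (12266, 12336, "MTTL2", "tRNA", "+"),
    (12337, 14148, "MTND5", "protein-coding", "+"),
    (14149, 14673, "MTND6", "protein-coding", "-"),
    (14674, 14742, "MTTE", "tRNA", "-"),
    (14747, 15887, "MTCYB", "protein-coding", "+"),
    (15888, 15953, "MTTT", "tRNA", "+"),
    (15956, 16023, "MTTP", "tRNA", "-"),
    (16024, 576, "CR", "control", "+"),  # control region, wraps the origin
]

#: (start, end, label) special regions: poly-C tract and light-strand origin
SPECIAL_TABLE: list[tuple[int, int, str]] = [
    (16184, 16193, "polyC"),
    (5721, 5798, "OriL"),
]

_STOPS = set(MT_CODON_TABLE.stop_codons)
_SAFE_CODONS = sorted(set(MT_CODON_TABLE.forward_table) - _STOPS)
_START_CODONS = ("ATG", "ATA")  # both methionine under the mitochondrial code


def _fill_gene(seq: list[str], start: int, end: int, strand: str, rng: random.Random) -> None:
    width = end - start + 1
    n_codons = width // 3
    codons = [rng.choice(_START_CODONS)]
    codons += [rng.choice(_SAFE_CODONS) for _ in range(n_codons - 1)]
    tail = "".join(rng.choice("ACGT") for _ in range(width - 3 * n_codons))
    cds = "".join(codons) + tail
    block = cds if strand == "+" else reverse_complement(cds)
    seq[start - 1 : end] = list(block)


def build_synthetic_rcrs() -> ReferenceModel:
    """Build the packaged synthetic reference, bit-for-bit reproducibly."""
    rng = random.Random(_BUILD_SEED)
    seq = [rng.choice("ACGT") for _ in range(RCRS_LENGTH)]

    for start, end, _label, cls, strand in GENE_TABLE:
        if cls == "protein-coding":
            _fill_gene(seq, start, end, strand, rng)

    # poly-C tract m.16184-16193, interrupted by T at 16189 as in the rCRS
    seq[16183:16193] = list("CCCCCTCCCC")
    # placeholder base
    seq[3107 - 1] = "N"
    # worked-example bases
    seq[250 - 1] = "T"  # control region
    seq[2905 - 1] = "A"  # MTRNR2 (rRNA)
    # m.5009: third position of a CTA leucine codon in MTND2 (A>G synonymous)
    seq[5007 - 1 : 5009] = list("CTA")

    genes = [GenomeRegion(s, e, lab, cls, strand) for s, e, lab, cls, strand in GENE_TABLE]
    special = {lab: GenomeRegion(s, e, lab) for s, e, lab in SPECIAL_TABLE}
    return ReferenceModel(name="rCRS-synthetic", sequence="".join(seq), genes=genes, special_regions=special)


def gene_table_text() -> str:
    """The packaged annotation table as tab-separated text."""
    lines = [
        "# synthetic rCRS gene map (canonical NC_012920.1 coordinates, overlaps trimmed)",
        f"#length={RCRS_LENGTH}",
        "# start\tend\tlabel\tclass\tstrand",
    ]
    for s, e, lab, cls, strand in GENE_TABLE:
        lines.append(f"{s}\t{e}\t{lab}\t{cls}\t{strand}")
    for s, e, lab in SPECIAL_TABLE:
        lines.append(f"{s}\t{e}\t{lab}\tspecial\t+")
    return "\n".join(lines) + "\n"


def fasta_text(model: ReferenceModel | None = None, width: int = 70) -> str:
    """FASTA rendering of the synthetic reference."""
    model = model or build_synthetic_rcrs()
    lines = [f">{model.name} synthetic mtDNA reference stand-in, {model.length} bp"]
    for i in range(0, model.length, width):
        lines.append(model.sequence[i : i + width])
    return "\n".join(lines) + "\n"


def synthetic_alt_reference(model: ReferenceModel | None = None, seed: int = 19) -> str:
    """A synthetic alternative mtDNA reference, emulating a non-rCRS strain.

    Mimics the hg19 chrM situation: two extra bases relative to the canonical
    sequence plus scattered single-base substitutions, so liftover has real
    work to do. Returns the alternative sequence (length 16,571).
    """
    model = model or build_synthetic_rcrs()
    rng = random.Random(seed)
    seq = list(model.sequence)
    # ~40 scattered substitutions away from N and the poly-C tract
    n_subs = 40
    done = set()
    while len(done) < n_subs:
        pos = rng.randrange(1, RCRS_LENGTH + 1)
        if pos in done or pos == 3107 or 16184 <= pos <= 16193:
            continue
        cur = seq[pos - 1]
        seq[pos - 1] = rng.choice([b for b in "ACGT" if b != cur])
        done.add(pos)
    # two single-base insertions (after m.309 and after m.3106, echoing the
    # length difference between hg19 chrM and the rCRS)
    seq.insert(3106, rng.choice("ACGT"))
    seq.insert(309, rng.choice("ACGT"))
    return "".join(seq)
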