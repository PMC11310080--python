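"""DNA grammar of the dual-CRISPR oligo and expression cassette.

The synthesized oligo carries only the two 20-nt protospacers (plus, in
v2, a 10-nt barcode) between fixed flanks and linkers; the full expression
cassette is produced after the second cloning step, when the two tracrRNA
scaffolds are inserted between the protospacers.  Two convergent RNA Pol
III promoters (U6 and H1) drive the two guides, so the H1-side protospacer
appears reverse-complemented on the U6 (top) strand.

All constants are uppercase-insensitive on comparison; the mixed case of
the linkers mirrors the ordered-oligo templates.
"""

from __future__ import annotations

import random

# --- synthesized-oligo templates ------------------------------------------
OLIGO_FLANK5 = "ATCTTGTGGAAAGGACGAAACACCG"           # 25 nt, ends in the U6 CACCG junction
V1_LINKER = "gttttgagacgggatccCGTCTCAAAAC"           # 28 nt, carries the BsmBI site
V2_LINKER1 = "gttttagagctaGAAAtagcaagttGAGACG"       # 31 nt
V2_LINKER2 = "CGTCTCAACTTGCTATTTCTAGCTCTAAAAC"       # 31 nt
OLIGO_FLANK3 = "CGGGAAAGAGTGGTCTCATACAGAACTTAT"      # 30 nt
BARCODE_LEN = 10

V1_OLIGO_LEN = len(OLIGO_FLANK5) + 20 + len(V1_LINKER) + 20 + len(OLIGO_FLANK3)
V2_OLIGO_LEN = (len(OLIGO_FLANK5) + 20 + len(V2_LINKER1) + BARCODE_LEN
                + len(V2_LINKER2) + 20 + len(OLIGO_FLANK3))

# --- read-processing anchors (promoter-proximal fixed sequence) -----------
U6_ANCHOR = "ATATATCTTGTGGAAAGGACGAAA"
H1_ANCHOR = "ATAAGTTCTGTATGAGACCACTCTT"
U6_JUNCTION = "CACCG"   # fixed bases between the U6 anchor and protospacer
H1_JUNCTION = "TCCCG"   # fixed bases between the H1 anchor and protospacer

# Standard SpCas9 sgRNA scaffold (tracrRNA fusion), 76 nt.
SCAFFOLD = ("GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCG"
            "TTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC")
SCAFFOLD_PREFIX = SCAFFOLD[:20]           # "GTTTTAGAGCTAGAAATAGC"
TRACR_ID = SCAFFOLD[20:30]                # "AAGTTAAAAT", scaffold pos 21-30

# Type-IIS recognition sites used to open the vector during cloning.
RESTRICTION_SITES = {
    "BsmBI": ("CGTCTC", "GAGACG"),
    "BbsI": ("GAAGAC", "GTCTTC"),
}

SCAFFOLD_GAP = {"v1": 50, "v2": 200}

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _validate_protospacer(seq: str, label: str) -> str:
    seq = seq.upper()
    if len(seq) != 20 or set(seq) - set("ACGT"):
        raise ValueError(f"{label}: protospacer must be 20 nt of ACGT, got {seq!r}")
    for enzyme, sites in RESTRICTION_SITES.items():
        for site in sites:
            if site in seq:
                raise ValueError(
                    f"{label}: protospacer contains {enzyme} recognition site {site}"
                )
    return seq


def forbidden_site_in(protospacer: str) -> str | None:
    """Name of the first type-IIS site found in the protospacer, if any."""
    seq = protospacer.upper()
    for enzyme, sites in RESTRICTION_SITES.items():
        for site in sites:
            if site in seq:
                return enzyme
    return None


def assemble_oligo_sequence(guide_u6: str, guide_h1: str, version: str,
                            barcode: str | None = None) -> str:
    """Exact synthesized-oligo string for one guide pair.

    The H1-side protospacer is inserted as its reverse complement so that,
    read from the convergent H1 promoter, the transcribed guide matches the
    genomic target.
    """
    g1 = _validate_protospacer(guide_u6, "guide_u6")
    g2 = _validate_protospacer(guide_h1, "guide_h1")
    if version == "v1":
        return OLIGO_FLANK5 + g1 + V1_LINKER + revcomp(g2) + OLIGO_FLANK3
    if version == "v2":
        if not barcode:
            raise ValueError("v2 oligos require a 10-nt barcode")
        barcode = barcode.upper()
        if len(barcode) != BARCODE_LEN or set(barcode) - set("ACGT"):
            raise ValueError(f"barcode must be {BARCODE_LEN} nt of ACGT, got {barcode!r}")
        return (OLIGO_FLANK5 + g1 + V2_LINKER1 + barcode + V2_LINKER2
                + revcomp(g2) + OLIGO_FLANK3)
    raise ValueError(f"unknown library version {version!r}")


def parse_oligo_sequence(sequence: str) -> tuple[str, str, str, str]:
    """Invert :func:`assemble_oligo_sequence`.

    Returns ``(version, guide_u6, guide_h1, barcode)``; barcode is ``""``
    for v1.  Comparison is case-insensitive.
    """
    seq = sequence.upper()
    a, b = len(OLIGO_FLANK5), len(OLIGO_FLANK3)
    if not (seq.startswith(OLIGO_FLANK5.upper()) and seq.endswith(OLIGO_FLANK3.upper())):
        raise ValueError("oligo does not carry the fixed 5'/3' flanks")
    if len(seq) == V1_OLIGO_LEN and seq[a + 20:a + 20 + len(V1_LINKER)] == V1_LINKER.upper():
        g1 = seq[a:a + 20]
        g2 = revcomp(seq[a + 20 + len(V1_LINKER):len(seq) - b])
        return "v1", g1, g2, ""
    if (len(seq) == V2_OLIGO_LEN
            and seq[a + 20:a + 20 + len(V2_LINKER1)] == V2_LINKER1.upper()):
        p = a + 20 + len(V2_LINKER1)
        barcode = seq[p:p + BARCODE_LEN]
        p += BARCODE_LEN
        if seq[p:p + len(V2_LINKER2)] != V2_LINKER2.upper():
            raise ValueError("v2 oligo second linker does not match the template")
        p += len(V2_LINKER2)
        g2 = revcomp(seq[p:p + 20])
        return "v2", seq[a:a + 20], g2, barcode
    raise ValueError("oligo length/linker does not match the v1 or v2 template")


def _make_spacer(length: int, seed: int = 2024) -> str:
    """Deterministic neutral 'nonsense' spacer for the inter-scaffold gap.

    Constraints: GC content 40-60%, no 6-mer shared with the promoter
    anchors or scaffold (either strand), and no type-IIS recognition site.
    """
    forbidden: set[str] = set()
    for ref in (U6_ANCHOR, H1_ANCHOR, SCAFFOLD):
        for s in (ref, revcomp(ref)):
            forbidden.update(s[i:i + 6] for i in range(len(s) - 5))
    for sites in RESTRICTION_SITES.values():
        forbidden.update(sites)
    rng = random.Random(seed)
    while True:
        seq = "".join(rng.choice("ACGT") for _ in range(length))
        gc = (seq.count("G") + seq.count("C")) / length
        if not 0.40 <= gc <= 0.60:
            continue
        kmers = {seq[i:i + 6] for i in range(len(seq) - 5)}
        if kmers & forbidden:
            continue
        return seq


SPACER = {"v1": _make_spacer(50), "v2": _make_spacer(200)}


def build_cassette_sequence(guide_u6: str, guide_h1: str, version: str) -> str:
    """Top-strand sequence of the post-cloning expression cassette.

    Layout: U6 anchor -> CACCG -> guide1 -> scaffold -> neutral spacer ->
    scaffold (reverse strand) -> guide2 (reverse complement) -> TCCCG/H1
    anchor (reverse strand).  The spacer length sets the inter-scaffold
    gap: 50 bp (v1) or 200 bp (v2).
    """
    g1 = _validate_protospacer(guide_u6, "guide_u6")
    g2 = _validate_protospacer(guide_h1, "guide_h1")
    if version not in SPACER:
        raise ValueError(f"unknown library version {version!r}")
    u6_side = U6_ANCHOR + U6_JUNCTION + g1 + SCAFFOLD
    h1_side = H1_ANCHOR + H1_JUNCTION + g2 + SCAFFOLD
    return u6_side + SPACER[version] + revcomp(h1_side)
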