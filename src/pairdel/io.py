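"""File I/O: BED, TSV, FASTA/FASTQ, MTX and YAML truth files.

Coordinates follow the BED dialect (0-based half-open) everywhere.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import CandidateGuide, GuidePair, LibraryDesign, TargetRegion


def read_regions_bed(path) -> list[TargetRegion]:
    """BED with name = region_id; optional 5th column = kind."""
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            kind = fields[4] if len(fields) > 4 and fields[4] in {
                "UCE", "VISTA", "predicted_enhancer", "control", "de_novo"
            } else "predicted_enhancer"
            regions.append(TargetRegion(region_id=name, chrom=chrom,
                                        start=start, end=end, kind=kind))
    return regions


def read_intervals_bed(path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def read_named_intervals_bed(path) -> list[tuple[str, str, int, int]]:
    """BED4 -> (name, chrom, start, end) rows (e.g. cluster or TAD files)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
            out.append((name, f[0], int(f[1]), int(f[2])))
    return out


GUIDE_COLUMNS = ["guide_id", "chrom", "cut_site", "strand", "protospacer",
                 "efficacy", "top5_offtarget", "top10_offtarget"]


def read_guides_tsv(path) -> list[CandidateGuide]:
    df = pd.read_csv(path, sep="\t")
    return [CandidateGuide(
        guide_id=str(r.guide_id), chrom=str(r.chrom), cut_site=int(r.cut_site),
        strand=str(r.strand), protospacer=str(r.protospacer),
        efficacy=float(r.efficacy), top5_offtarget=float(r.top5_offtarget),
        top10_offtarget=float(r.top10_offtarget)) for r in df.itertuples()]


def write_guides_tsv(guides: Iterable[CandidateGuide], path) -> None:
    pd.DataFrame([{
        "guide_id": g.guide_id, "chrom": g.chrom, "cut_site": g.cut_site,
        "strand": g.strand, "protospacer": g.protospacer,
        "efficacy": g.efficacy, "top5_offtarget": g.top5_offtarget,
        "top10_offtarget": g.top10_offtarget} for g in guides]
    ).to_csv(path, sep="\t", index=False)


def design_to_frame(library: LibraryDesign) -> pd.DataFrame:
    barcode = {o.pair_id: o.barcode for o in library.oligos}
    rows = []
    for pair in library.all_pairs:
        rows.append({
            "pair_id": pair.pair_id, "region_id": pair.region_id,
            "strategy": pair.strategy, "chrom": pair.guide_u6.chrom,
            "protospacer_u6": pair.guide_u6.protospacer,
            "protospacer_h1": pair.guide_h1.protospacer,
            "cut_u6": pair.guide_u6.cut_site, "cut_h1": pair.guide_h1.cut_site,
            "deletion_start": pair.expected_deletion[0],
            "deletion_end": pair.expected_deletion[1],
            "barcode": barcode.get(pair.pair_id, "")})
    return pd.DataFrame(rows)


def write_design_tsv(library: LibraryDesign, path) -> None:
    design_to_frame(library).to_csv(path, sep="\t", index=False)


def read_design_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    SeqIO.write((SeqRecord(Seq(seq), id=name, description="")
                 for name, seq in records), str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="pair_id")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="pair_id")


def write_matrix_mtx(df: pd.DataFrame, prefix) -> None:
    """Dense frame -> MTX triplet (matrix.mtx, features.tsv, barcodes.tsv)."""
    from scipy import io as spio
    from scipy import sparse
    prefix = Path(prefix)
    prefix.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(prefix / "matrix.mtx"), sparse.csr_matrix(df.to_numpy()))
    (prefix / "features.tsv").write_text("\n".join(map(str, df.index)) + "\n")
    (prefix / "barcodes.tsv").write_text("\n".join(map(str, df.columns)) + "\n")


def read_matrix_mtx(prefix) -> pd.DataFrame:
    from scipy import io as spio
    prefix = Path(prefix)
    mat = spio.mmread(str(prefix / "matrix.mtx")).toarray()
    features = (prefix / "features.tsv").read_text().splitlines()
    barcodes = (prefix / "barcodes.tsv").read_text().splitlines()
    return pd.DataFrame(mat, index=features, columns=barcodes)


def write_truth_yaml(truth: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)


def read_truth_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def read_condition_yaml(path) -> dict[str, str]:
    """sample -> condition map."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return {str(k): str(v) for k, v in data.items()}
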