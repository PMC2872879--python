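"""File interchange: FASTA regions, TSV evidence, BED peaks, MEME PSSMs."""

from __future__ import annotations

import os
import warnings
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .evidence import EvidenceSet, make_evidence
from .index import Region
from .postprocess import BASES, Pssm
from .prep import GenomicInterval, Peak
from .search import MotifResult
from .significance import NullDistribution


class InputFormatError(ValueError):
    """A user-supplied file failed validation."""


# ---------------------------------------------------------------------------
# Regions and orthologs (FASTA)


def read_regions(path) -> List[Region]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputFormatError(f"no FASTA records in {path}")
    regions: List[Region] = []
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise InputFormatError(f"duplicate region id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise InputFormatError(f"region {rec.id!r} has an empty sequence")
        regions.append(Region(id=rec.id, sequence=seq))
    return regions


def write_regions(regions: Sequence[Region], path) -> None:
    records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in regions
    ]
    SeqIO.write(records, str(path), "fasta")


def read_orthologs(directory, regions: Sequence[Region]) -> List[Region]:
    """Attach ortholog sequences from one FASTA per species in a directory.

    File stems name the species; record ids must match primary region ids.
    Regions missing from a species file simply have no ortholog there.
    """
    by_id = {r.id: r for r in regions}
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix in (".fa", ".fasta", ".fna"))
    if not files:
        raise InputFormatError(f"no FASTA files in ortholog directory {directory}")
    for path in files:
        species = path.stem
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id not in by_id:
                raise InputFormatError(
                    f"ortholog record {rec.id!r} in {path.name} matches no primary region"
                )
            by_id[rec.id].orthologs[species] = str(rec.seq)
    return regions


# ---------------------------------------------------------------------------
# Evidence (two-column TSV)


def read_evidence(
    path,
    evidence_type: str,
    region_ids: Optional[Sequence[str]] = None,
    *,
    lenient: bool = False,
    **kwargs,
) -> EvidenceSet:
    """Two-column (region id, raw value) table -> transformed EvidenceSet.

    With ``region_ids`` the table is cross-validated: unknown ids are an
    error (or dropped with a warning when ``lenient``).
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=["region_id", "value"], comment="#")
        values = df["value"].astype(float)
    except (ValueError, pd.errors.ParserError) as exc:
        raise InputFormatError(f"cannot parse evidence table {path}: {exc}") from exc
    ids = df["region_id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise InputFormatError(f"duplicate region ids in evidence table {path}")
    if region_ids is not None:
        known = set(region_ids)
        unknown = [i for i in ids if i not in known]
        if unknown:
            if not lenient:
                raise InputFormatError(
                    f"{len(unknown)} evidence rows reference unknown regions "
                    f"(first: {unknown[:5]})"
                )
            warnings.warn(f"dropping {len(unknown)} evidence rows with unknown region ids")
            keep = [i for i, rid in enumerate(ids) if rid in known]
            ids = [ids[i] for i in keep]
            values = values.iloc[keep]
    return make_evidence(ids, values.to_numpy(), evidence_type, **kwargs)


def write_evidence(ev: EvidenceSet, path, *, raw: bool = True) -> None:
    vals = ev.raw if (raw and ev.raw is not None) else ev.values
    pd.DataFrame({"region_id": ev.ids, "value": np.asarray(vals)}).to_csv(
        path, sep="\t", header=False, index=False
    )


def align_regions_evidence(
    regions: Sequence[Region], ev: EvidenceSet, *, lenient: bool = False
) -> Tuple[List[Region], EvidenceSet]:
    """Intersect a region set with its evidence table, preserving region order."""
    have = set(ev.ids)
    missing = [r.id for r in regions if r.id not in have]
    if missing:
        if not lenient:
            raise InputFormatError(
                f"{len(missing)} regions lack evidence (first: {missing[:5]}); "
                "use lenient mode to drop them"
            )
        warnings.warn(f"dropping {len(missing)} regions without evidence")
    kept = [r for r in regions if r.id in have]
    return kept, ev.reordered([r.id for r in kept])


# ---------------------------------------------------------------------------
# BED peaks / regions


def read_peaks_bed(path) -> List[Peak]:
    """BED with score in column 5; optional column 7 is the summit position
    (absolute coordinate); defaults to the interval midpoint."""
    peaks: List[Peak] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise InputFormatError(f"{path}:{ln}: need >= 5 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            score = float(parts[4])
            summit = int(parts[6]) if len(parts) > 6 and parts[6] != "." else (start + end) // 2
            peaks.append(Peak(chrom=chrom, start=start, end=end, score=score, summit=summit))
    if not peaks:
        raise InputFormatError(f"no peaks in {path}")
    return peaks


def write_intervals_bed(intervals: Sequence[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\n")


def extract_interval_sequences(intervals: Sequence[GenomicInterval], fasta_path) -> List[Region]:
    """Pull region sequences for genomic intervals out of a genome FASTA."""
    from pyfaidx import Fasta

    genome = Fasta(str(fasta_path))
    regions = []
    for iv in intervals:
        seq = str(genome[iv.chrom][iv.start : iv.end])
        regions.append(Region(id=iv.id, sequence=seq))
    return regions


# ---------------------------------------------------------------------------
# Reads table (SAM-derived tabular: read id, chrom, pos, strand, n_hits)


def read_alignments_tsv(path):
    df = pd.read_csv(
        path, sep="\t", header=None, names=["read_id", "chrom", "pos", "strand", "n_hits"]
    )
    return list(df.itertuples(index=False, name=None))


def write_alignments_tsv(alignments, path) -> None:
    pd.DataFrame(alignments).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# MEME minimal motif format


def write_meme(pssms: Mapping[str, Pssm], path, *, background=None) -> None:
    bg = background or dict(zip(BASES, [0.25] * 4))
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {bg[b]:.5f}" for b in BASES) + "\n\n")
        for name, pssm in pssms.items():
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pssm.width} "
                f"nsites= {max(pssm.n_sites, 1)} E= 0\n"
            )
            for row in pssm.matrix:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme(path) -> Dict[str, Pssm]:
    pssms: Dict[str, Pssm] = {}
    name = None
    rows: List[List[float]] = []
    expect = 0
    nsites = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                name = line.split()[1]
            elif line.startswith("letter-probability matrix"):
                fields = dict(
                    zip(*[iter(line.split(":")[1].replace("=", " ").split())] * 2)
                )
                expect = int(fields["w"])
                nsites = int(fields.get("nsites", 0))
                rows = []
            elif name is not None and expect and line and (line[0].isdigit() or line[0] == "."):
                rows.append([float(x) for x in line.split()])
                if len(rows) == expect:
                    mat = np.asarray(rows)
                    mat /= mat.sum(axis=1, keepdims=True)
                    pssms[name] = Pssm(mat, n_sites=nsites)
                    name, rows, expect = None, [], 0
    if not pssms:
        raise InputFormatError(f"no motifs parsed from {path}")
    return pssms


def write_pssm_tsv(pssm: Pssm, path) -> None:
    pd.DataFrame(pssm.matrix, columns=list(BASES)).to_csv(path, sep="\t", index_label="position")


# ---------------------------------------------------------------------------
# Reports


def write_results_tsv(results: Sequence[MotifResult], path) -> None:
    rows = [
        {
            "rank": i + 1,
            "motif": r.motif,
            "score": r.score,
            "set_size": len(r.positive_set),
            "seed": r.seed,
            "steps": r.steps,
            "p_value": "" if r.p_value is None else r.p_value,
        }
        for i, r in enumerate(results)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_cluster_report(clusters, path) -> None:
    rows = []
    for i, c in enumerate(clusters):
        rep = c.representative
        rows.append(
            {
                "cluster": i + 1,
                "representative": rep.motif,
                "score": rep.score,
                "p_value": "" if rep.p_value is None else rep.p_value,
                "n_members": len(c.members),
                "members": ",".join(m.motif for m in c.members),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_null_tsv(null: NullDistribution, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# gamma_shape\t{null.shape}\n")
        fh.write(f"# gamma_scale\t{null.scale}\n")
        fh.write(f"# offset\t{null.offset}\n")
        fh.write(f"# n_perm\t{null.n_perm}\n")
        fh.write(f"# rng_seed\t{null.rng_seed}\n")
        for s in null.scores:
            fh.write(f"{s}\n")
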