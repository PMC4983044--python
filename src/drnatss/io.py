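"""Readers and writers for the package's on-disk formats.

FASTA goes through Biopython, GFF3 reading through gffutils. Wiggle
(variableStep, one file per strand per library) has no text reader in the
scientific Python stack, so a minimal one lives here. Tabular files are
plain TSV via pandas.
"""

from __future__ import annotations

import re
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import Feature, GenomeModel
from .tracks import CoverageTrack

_STRAND_TAG = {"+": "fwd", "-": "rev"}
_TAG_STRAND = {v: k for k, v in _STRAND_TAG.items()}
_WIG_NAME = re.compile(r"^rep(\d+)_(minus_tex|plus_tex)_(fwd|rev)\.wig$")


# ---------------------------------------------------------------- FASTA

def write_fasta(genome: GenomeModel, path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------- GFF3

def write_gff3(features: list[Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.feature_id};category={f.category}"
            fh.write(
                f"{f.replicon}\tdrnatss\tgene\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> list[Feature]:
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    features = []
    for rec in db.all_features():
        features.append(
            Feature(
                feature_id=rec.id,
                replicon=rec.seqid,
                start=rec.start,
                end=rec.end,
                strand=rec.strand,
                category=rec.attributes.get("category", ["CDS"])[0],
            )
        )
    return features


# ---------------------------------------------------------------- wiggle

def track_filename(track: CoverageTrack) -> str:
    return f"rep{track.replicate}_{track.treatment}_{_STRAND_TAG[track.strand]}.wig"


def write_wiggle(track: CoverageTrack, path: str | Path) -> None:
    """variableStep wiggle; only non-zero positions are written."""
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{track.library}_{_STRAND_TAG[track.strand]}"\n')
        fh.write(f"variableStep chrom={track.replicon}\n")
        (nz,) = np.nonzero(track.values)
        for i in nz:
            v = track.values[i]
            text = str(int(v)) if float(v).is_integer() else repr(float(v))
            fh.write(f"{i + 1} {text}\n")


def read_wiggle(path: str | Path, lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Parse a variableStep wiggle into dense per-replicon arrays."""
    out: dict[str, np.ndarray] = {}
    current: np.ndarray | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("track"):
                continue
            if line.startswith("variableStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                if chrom not in lengths:
                    raise ValueError(f"unknown replicon {chrom!r} in {path}")
                current = out.setdefault(chrom, np.zeros(lengths[chrom]))
            elif line.startswith("fixedStep"):
                raise ValueError("fixedStep wiggle is not produced by this package")
            else:
                if current is None:
                    raise ValueError(f"data line before variableStep header in {path}")
                pos_s, val_s = line.split()
                current[int(pos_s) - 1] = float(val_s)
    return out


def write_coverage_dir(tracks: list[CoverageTrack], outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for track in tracks:
        p = outdir / track_filename(track)
        write_wiggle(track, p)
        paths.append(p)
    return paths


def load_coverage_dir(
    directory: str | Path, lengths: dict[str, int], mapped_reads: dict[str, float]
) -> list[CoverageTrack]:
    """Load every ``rep*_{minus,plus}_tex_{fwd,rev}.wig`` in a directory."""
    directory = Path(directory)
    tracks = []
    for path in sorted(directory.iterdir()):
        m = _WIG_NAME.match(path.name)
        if not m:
            continue
        rep, treatment, tag = int(m.group(1)), m.group(2), m.group(3)
        library = f"rep{rep}_{treatment}"
        if library not in mapped_reads:
            raise ValueError(f"no mapped-read count for library {library}")
        for replicon, values in read_wiggle(path, lengths).items():
            tracks.append(
                CoverageTrack(
                    replicon=replicon,
                    strand=_TAG_STRAND[tag],
                    values=values,
                    treatment=treatment,
                    replicate=rep,
                    mapped_reads=mapped_reads[library],
                )
            )
    if not tracks:
        raise FileNotFoundError(f"no coverage tracks found in {directory}")
    return tracks


# ---------------------------------------------------------------- TSV

def write_mapped_reads(mapped: dict[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"library": list(mapped), "mapped_reads": list(mapped.values())}
    ).to_csv(path, sep="\t", index=False)


def read_mapped_reads(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["library"], df["mapped_reads"].astype(float)))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    # round_trip float parsing so written fixtures reload bit-identically
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
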