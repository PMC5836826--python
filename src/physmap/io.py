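"""Readers and writers for the pipeline's plain-text formats.

Bands file dialect (bit-exact): per clone one header line
``>{owner_id} {band_count}`` followed by one integer band value per line;
records concatenated; UTF-8 with LF endings.  The reader tolerates blank
lines between records and CRLF input; the writer always emits LF.
Sequences travel as FASTA, repeat annotations as BED (0-based,
half-open), tables as TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fingerprint import Fingerprint


# -- bands dialect ----------------------------------------------------------

def write_bands(fps: list[Fingerprint], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for fp in fps:
            fh.write(f">{fp.owner} {fp.band_count}\n")
            for v in fp.bands:
                fh.write(f"{int(v)}\n")


def read_bands(path: str | Path) -> list[Fingerprint]:
    path = Path(path)
    fps: list[Fingerprint] = []
    seen: set[str] = set()
    owner: str | None = None
    expect = 0
    bands: list[int] = []

    def flush(lineno: int) -> None:
        nonlocal owner, bands
        if owner is None:
            return
        if len(bands) != expect:
            raise ValueError(
                f"{path}:{lineno}: clone {owner!r} lists {len(bands)} bands "
                f"but header declares {expect}")
        fps.append(Fingerprint(owner, np.sort(np.array(bands, dtype=np.int64))))
        owner, bands = None, []

    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n").strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                parts = line[1:].split()
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: malformed header {line!r}")
                owner = parts[0]
                if owner in seen:
                    raise ValueError(f"{path}:{lineno}: duplicate clone id {owner!r}")
                seen.add(owner)
                try:
                    expect = int(parts[1])
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: non-integer band count "
                                     f"in header {line!r}") from None
                bands = []
            else:
                if owner is None:
                    raise ValueError(f"{path}:{lineno}: band value before any header")
                try:
                    bands.append(int(line))
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: non-integer band value "
                                     f"{line!r} (clone {owner!r})") from None
        flush(lineno + 1 if "lineno" in locals() else 1)
    return fps


# -- FASTA / BED / TSV ------------------------------------------------------

def write_fasta(records: dict[str, str], path: str | Path) -> None:
    SeqIO.write((SeqRecord(Seq(seq), id=name, description="")
                 for name, seq in records.items()), str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(intervals: list[tuple[int, int, str]], chrom: str,
              path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for a, b, name in intervals:
            fh.write(f"{chrom}\t{a}\t{b}\t{name}\n")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def clone_table(clone_set) -> pd.DataFrame:
    rows = []
    for cid, src, a, b in clone_set.clones:
        plate, row, col = clone_set.plate_layout[cid]
        rows.append({"clone_id": cid, "source": src, "start": a, "end": b,
                     "plate": plate, "row": row, "col": col})
    return pd.DataFrame(rows)


def marker_table(chrom) -> pd.DataFrame:
    return pd.DataFrame(
        [{"marker_id": mid, "type": mtype, "position": pos}
         for mid, mtype, pos in chrom.marker_loci])


def contig_table(contigs) -> pd.DataFrame:
    return pd.DataFrame(
        [{"contig_id": c.id, "n_clones": c.n_clones,
          "consensus_bands": c.consensus_band_count,
          "est_kb": round(c.estimated_length_kb, 1),
          "reliability": c.reliability, "depth": round(c.mean_depth, 2),
          "clone_order": ",".join(map(str, c.clones))}
         for c in contigs])


def edge_table(graph) -> pd.DataFrame:
    return pd.DataFrame(
        [{"clone_a": a, "clone_b": b, "shared": d["shared"], "score": d["score"]}
         for a, b, d in sorted(graph.edges(data=True))])


def anchor_table(records) -> pd.DataFrame:
    rows = []
    for k, r in enumerate(records, start=1):
        if isinstance(r.position, tuple):
            beg, end = r.position
        else:
            beg = end = r.position
        rows.append({"object": r.subject, "object_beg": beg, "object_end": end,
                     "part_number": k, "component_type": "W",
                     "component_id": r.subject, "evidence": r.evidence,
                     "stage": r.stage})
    return pd.DataFrame(rows)


# -- config / JSON ----------------------------------------------------------

def write_yaml(data: dict, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_json(data, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        json.dump(data, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, tuple)):
        return sorted(obj) if isinstance(obj, set) else list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
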