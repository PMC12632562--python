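"""Readers and writers for the plain-text interchange formats.

TSV tables carry a header row and may be preceded by `# key=value`
provenance comments.  Event coordinates travel as BED6 (0-based
half-open, strand used; the name field packs event_id|gene|class).  Exon
sequences travel as FASTA with the exon interval recorded in the record
description (`exon_start=.. exon_end=..`, 0-based half-open within the
record).  Truth tables are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_tsv(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_events_bed(events: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, r in events.iterrows():
            name = f"{r['event_id']}|{r['gene']}|{r['event_class']}"
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t{name}\t0\t{r['strand']}\n")


def read_events_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            eid, gene, cls = name.split("|")
            rows.append((eid, gene, cls, chrom, int(start), int(end), strand))
    return pd.DataFrame(rows, columns=["event_id", "gene", "event_class",
                                       "chrom", "start", "end", "strand"])


def write_exon_fasta(records: list[dict], path) -> None:
    seq_records = [
        SeqRecord(
            Seq(r["sequence"]), id=r["exon_id"],
            description=f"exon_start={r['exon_start']} exon_end={r['exon_end']}",
        )
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


def read_exon_fasta(path) -> list[dict]:
    out = []
    with open(path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    for rec in records:
        fields = dict(kv.split("=") for kv in rec.description.split()[1:]
                      if "=" in kv)
        out.append({
            "exon_id": rec.id,
            "sequence": str(rec.seq).upper(),
            "exon_start": int(fields.get("exon_start", 0)),
            "exon_end": int(fields.get("exon_end", len(rec.seq))),
        })
    return out


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=str)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
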