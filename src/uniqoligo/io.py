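"""FASTA input, result tables, and ground-truth files.

FASTA parsing is delegated to Biopython's ``SeqIO``; record ids are the
first whitespace-delimited token of each header and sequences are
uppercased on load.  All output coordinates are 0-based half-open (BED
convention); the oligo string in each row disambiguates any off-by-one
concern.
"""

from __future__ import annotations

import csv
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import EstDatabase
from .search import UniquenessResult
from .synth import PlantSpec

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_results",
    "write_ground_truth",
]


def read_fasta(path: "str | Path") -> EstDatabase:
    """Load a multi-record FASTA file (wrapped or unwrapped lines).

    Raises ``ValueError`` on duplicate ids or empty records.
    """
    records: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty record {rec.id!r} in {path}")
        records.append((rec.id, seq))
    return EstDatabase(records=records)  # raises on duplicate ids


def write_fasta(db: EstDatabase, path: "str | Path", width: int = 70) -> None:
    """Write the database as wrapped FASTA."""
    recs = [
        SeqRecord(Seq(seq), id=rec_id, description="") for rec_id, seq in db
    ]
    writer_width = max(1, width)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=writer_width)
        writer.write_file(recs)


def write_results(
    result: UniquenessResult,
    db: EstDatabase,
    out_prefix: "str | Path",
    bed: bool = False,
) -> list[Path]:
    """Write the unique-oligo table and the per-sequence summary.

    Produces ``<prefix>.unique.tsv`` (seq_id, start, end, oligo),
    ``<prefix>.summary.tsv`` (per-sequence clean-window/non-unique/unique
    counts plus a TOTAL row and the search parameters), and optionally
    ``<prefix>.unique.bed``.  Returns the written paths.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    uniq_path = prefix.with_suffix(prefix.suffix + ".unique.tsv")
    with open(uniq_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["seq_id", "start", "end", "oligo"])
        for i, rec_id in enumerate(db.ids):
            for start, oligo in result.unique_oligos[i]:
                w.writerow([rec_id, start, start + len(oligo), oligo])
    written.append(uniq_path)

    p = result.params
    summary_path = prefix.with_suffix(prefix.suffix + ".summary.tsv")
    with open(summary_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if p is not None:
            w.writerow(["# l", p.l, "d", p.d, "scheme", p.scheme.value,
                        "q", p.q, "k", p.k, "m", p.m])
        w.writerow(["seq_id", "clean_windows", "nonunique", "unique"])
        tot_w = tot_n = tot_u = 0
        for i, rec_id in enumerate(db.ids):
            n_non = len(result.nonunique[i])
            n_uni = len(result.unique_oligos[i])
            w.writerow([rec_id, n_non + n_uni, n_non, n_uni])
            tot_w += n_non + n_uni
            tot_n += n_non
            tot_u += n_uni
        w.writerow(["TOTAL", tot_w, tot_n, tot_u])
    written.append(summary_path)

    if bed:
        bed_path = prefix.with_suffix(prefix.suffix + ".unique.bed")
        with open(bed_path, "w") as fh:
            for i, rec_id in enumerate(db.ids):
                for start, oligo in result.unique_oligos[i]:
                    fh.write(f"{rec_id}\t{start}\t{start + len(oligo)}\n")
        written.append(bed_path)
    return written


def write_ground_truth(
    plants: list[PlantSpec], db: EstDatabase, path: "str | Path"
) -> None:
    """TSV of planted windows: seq_id, start, role, substitutions."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["seq_id", "start", "role", "substitutions"])
        for spec in plants:
            for role, (si, start) in (
                ("donor", spec.donor),
                ("recipient", spec.recipient),
            ):
                w.writerow([db.ids[si], start, role, spec.substitutions])
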