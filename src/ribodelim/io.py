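"""File formats: FASTA with a Vienna dot-bracket sidecar, tables, run logs.

The sidecar convention pairs each FASTA record with one dot-bracket line in
a ``.db`` file: ``>id`` then the structure string, in the same order as the
FASTA.  Sequences are written with ``U`` (transcript convention).
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .structures import StructuredSequence


def write_fasta_vienna(records: list[StructuredSequence], fasta_path, struct_path) -> None:
    seqs = [SeqRecord(Seq(r.nucleotides), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(fasta_path), "fasta")
    with open(struct_path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.structure}\n")


def read_fasta_vienna(fasta_path, struct_path) -> list[StructuredSequence]:
    structures: dict[str, str] = {}
    with open(struct_path) as fh:
        current = None
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].split()[0]
            else:
                if current is None:
                    raise ValueError(f"{struct_path}: structure line before any header")
                structures[current] = structures.get(current, "") + line
    out = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in structures:
            raise ValueError(f"{struct_path}: no structure for record {rec.id!r}")
        out.append(StructuredSequence(rec.id, str(rec.seq), structures[rec.id]))
    return out


def read_sequences(path) -> list[str]:
    """Read sequences from FASTA or FASTQ, optionally gzip-compressed.

    The format is inferred from the filename (``.fq``/``.fastq`` means
    FASTQ, anything else FASTA); returns plain uppercase strings for the
    k-mer pipeline.
    """
    import gzip

    name = str(path)
    opener = gzip.open if name.endswith(".gz") else open
    stem = name[:-3] if name.endswith(".gz") else name
    fmt = "fastq" if stem.endswith((".fq", ".fastq")) else "fasta"
    with opener(name, "rt") as fh:
        return [str(rec.seq).upper() for rec in SeqIO.parse(fh, fmt)]


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_log(out_dir, stage: str, params: dict, inputs: list | None = None) -> Path:
    """Machine-readable provenance: stage, parameters, input checksums."""
    from importlib.metadata import PackageNotFoundError, version

    try:
        pkg_version = version("ribodelim")
    except PackageNotFoundError:  # pragma: no cover
        pkg_version = "unknown"
    log = {
        "stage": stage,
        "version": pkg_version,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "parameters": params,
        "inputs": [{"path": str(p), "sha256": file_sha256(p)} for p in (inputs or [])],
    }
    out = Path(out_dir) / f"run_log_{stage}.json"
    with open(out, "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True, default=str)
    return out
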