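"""FASTA / deme-map / JSON input-output with provenance.

Sequence ids are opaque strings (the simulator uses
``sampleID|demeLabel[|alleleCopy]``); the deme map is a two-column TSV
with header ``sample_id<TAB>deme``.  All JSON outputs carry a provenance
block (package version, configuration hash, root seed) so any artifact
is regenerable from config + seed alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)


def read_fasta(path) -> dict[str, str]:
    """Read an aligned FASTA (wrapped lines, mixed case accepted)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"no sequences found in {path}")
    return out


def write_fasta(path, alignment: dict[str, str], width: int = 70) -> None:
    recs = [SeqRecord(Seq(s), id=i, description="") for i, s in alignment.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_deme_map(path) -> dict[str, str]:
    """Two-column TSV (sample_id, deme) with a header row."""
    out: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"deme map {path} must be a 2-column TSV with header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            sid, deme = parts[0], parts[1]
            if sid in out:
                raise ValueError(f"duplicate sample id {sid!r} in deme map")
            out[sid] = deme
    return out


def write_deme_map(path, deme_map: dict[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tdeme\n")
        for sid, deme in deme_map.items():
            fh.write(f"{sid}\t{deme}\n")


def check_consistency(alignment: dict[str, str], deme_map: dict[str, str]) -> dict[str, str]:
    """Cross-check ids; returns the deme map restricted to the alignment.

    Sequences without a deme assignment are an error; deme-map entries
    absent from the alignment are logged and dropped.
    """
    missing = sorted(set(alignment) - set(deme_map))
    if missing:
        raise ValueError("sequences without deme assignment: "
                         + ", ".join(missing[:10]) + ("..." if len(missing) > 10 else ""))
    extra = sorted(set(deme_map) - set(alignment))
    if extra:
        logger.warning("deme map lists %d sample(s) absent from the alignment "
                       "(ignored): %s%s", len(extra), ", ".join(extra[:5]),
                       "..." if len(extra) > 5 else "")
    return {sid: deme_map[sid] for sid in alignment}


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def provenance(config_obj, seed) -> dict:
    from phylodeme import __version__
    return {"package": "phylodeme", "version": __version__,
            "config_hash": config_hash(config_obj), "seed": seed}


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=float) + "\n")


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s [%(name)s] %(levelname)s: %(message)s",
    )
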