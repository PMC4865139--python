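"""Readers, writers and run configuration.

Conventions: user-facing coordinates are 1-based inclusive in every TSV;
BED output is 0-based half-open (the only exception, as the format
demands).  FASTA ids are the join key across profile, element and oligo
files.  Write-then-read round-trips reproduce the in-memory objects.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .oligo import Oligo
from .scan import CisElement, PerturbationProfile
from .sequences import RNA_BASES, UtrSequence

logger = logging.getLogger(__name__)


class FastaParseError(ValueError):
    """Malformed FASTA input; the message carries the offending line number."""


def read_fasta(path, whitespace_tolerant: bool = False) -> list[UtrSequence]:
    """Read a (DNA or RNA) FASTA file into normalized UTR sequences.

    Ids are headers up to the first whitespace; duplicate ids, empty
    records and non-nucleotide characters are parse errors naming the
    line.  With ``whitespace_tolerant`` internal blanks in sequence lines
    are dropped instead of rejected.
    """
    path = Path(path)
    records: list[UtrSequence] = []
    seen: dict[str, int] = {}
    current_id: str | None = None
    chunks: list[str] = []
    id_line = 0

    def flush(line_no: int) -> None:
        nonlocal current_id, chunks
        if current_id is None:
            return
        raw = "".join(chunks)
        if not raw:
            raise FastaParseError(f"record {current_id!r} (line {id_line}) has no sequence")
        try:
            records.append(UtrSequence.from_string(current_id, raw))
        except ValueError as exc:
            raise FastaParseError(f"record {current_id!r} (line {id_line}): {exc}") from exc
        current_id, chunks = None, []

    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush(line_no)
                current_id = line[1:].split()[0] if line[1:].split() else ""
                if not current_id:
                    raise FastaParseError(f"empty FASTA header at line {line_no}")
                if current_id in seen:
                    raise FastaParseError(
                        f"duplicate id {current_id!r} at line {line_no} "
                        f"(first seen at line {seen[current_id]})"
                    )
                seen[current_id] = line_no
                id_line = line_no
            else:
                if current_id is None:
                    raise FastaParseError(f"sequence before any header at line {line_no}")
                if any(c.isspace() for c in line.strip()) or " " in line.strip():
                    if whitespace_tolerant:
                        line = "".join(line.split())
                    else:
                        raise FastaParseError(
                            f"whitespace inside sequence at line {line_no}"
                        )
                chunks.append(line.strip())
    flush(-1)
    if not records:
        raise FastaParseError(f"no FASTA records in {path}")
    return records


def write_fasta(sequences, path) -> None:
    recs = []
    for seq in sequences:
        if isinstance(seq, UtrSequence):
            recs.append(SeqRecord(Seq(seq.to_source()), id=seq.id, description=""))
        else:  # Oligo
            header = f"{seq.name}|{seq.category}|{seq.chemistry}"
            recs.append(SeqRecord(Seq(seq.residues), id=header, description=""))
    SeqIO.write(recs, str(path), "fasta")


# ----------------------------------------------------------------------
# profile TSV
# ----------------------------------------------------------------------

def profile_to_frame(profile: PerturbationProfile) -> pd.DataFrame:
    """Tidy per-position table; signal columns are NaN outside valid windows."""
    L = profile.length
    w = profile.window
    signal = np.full(L, np.nan)
    scaled = np.full(L, np.nan)
    signal[: L - w + 1] = profile.signal
    scaled[: L - w + 1] = profile.signal_scaled
    return pd.DataFrame(
        {
            "seq_id": profile.seq_id,
            "pos": np.arange(1, L + 1),
            "wt_base": list(profile.residues) if profile.residues else [""] * L,
            "raw_ddg": profile.raw,
            "signal": signal,
            "signal_scaled": scaled,
        }
    )


def write_profile(profile: PerturbationProfile, path) -> None:
    frame = profile_to_frame(profile)
    with open(path, "w") as fh:
        fh.write(f"# window={profile.window} wild_type_dg={profile.wild_type_dg!r} "
                 f"engine={profile.engine}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_profile(path) -> PerturbationProfile:
    with open(path) as fh:
        header = fh.readline()
        meta = dict(tok.split("=", 1) for tok in header.lstrip("# ").split())
        frame = pd.read_csv(fh, sep="\t")
    window = int(meta["window"])
    raw = frame["raw_ddg"].to_numpy(dtype=float)
    n_sig = len(raw) - window + 1
    return PerturbationProfile(
        seq_id=str(frame["seq_id"].iloc[0]),
        wild_type_dg=float(meta["wild_type_dg"]),
        raw=raw,
        window=window,
        signal=frame["signal"].to_numpy(dtype=float)[:n_sig],
        signal_scaled=frame["signal_scaled"].to_numpy(dtype=float)[:n_sig],
        engine=meta.get("engine", "unknown"),
        residues="".join(frame["wt_base"].astype(str)) if frame["wt_base"].notna().all() else "",
    )


# ----------------------------------------------------------------------
# elements: TSV (1-based inclusive) and BED (0-based half-open)
# ----------------------------------------------------------------------

def elements_to_frame(elements) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "seq_id": e.seq_id,
                "start": e.start,
                "end": e.end,
                "peak_signal": e.peak_signal,
                "rank_label": e.rank_label,
                "annotation": e.annotation,
            }
            for e in elements
        ],
        columns=["seq_id", "start", "end", "peak_signal", "rank_label", "annotation"],
    )


def write_elements_tsv(elements, path) -> None:
    elements_to_frame(elements).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_elements_tsv(path) -> list[CisElement]:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        CisElement(
            seq_id=str(r.seq_id),
            start=int(r.start),
            end=int(r.end),
            peak_signal=float(r.peak_signal),
            rank_label=str(r.rank_label),
            annotation=str(r.annotation),
        )
        for r in frame.itertuples()
    ]


def write_elements_bed(elements, path) -> None:
    """BED6: chrom = seq_id, 0-based half-open, score = peak signal."""
    with open(path, "w") as fh:
        fh.write("# dgscan elements; BED 0-based half-open; name=rank_label\n")
        for e in elements:
            fh.write(
                f"{e.seq_id}\t{e.start - 1}\t{e.end}\t{e.rank_label}\t"
                f"{e.peak_signal:.6g}\t+\n"
            )


def read_elements_bed(path) -> list[CisElement]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, name, score, _strand = line.rstrip("\n").split("\t")
            out.append(
                CisElement(
                    seq_id=chrom,
                    start=int(start) + 1,
                    end=int(end),
                    peak_signal=float(score),
                    rank_label=name,
                )
            )
    return out


# ----------------------------------------------------------------------
# oligos
# ----------------------------------------------------------------------

def oligos_to_frame(oligos) -> pd.DataFrame:
    rows = []
    for o in oligos:
        start, end = o.target_interval if o.target_interval else ("", "")
        wobble_label = "GU_wobble" if o.chemistry == "RNA_2OME" else "GT_apposition"
        rows.append(
            {
                "name": o.name,
                "category": o.category,
                "chemistry": o.chemistry,
                "sequence": o.residues,
                "target_seq_id": o.target_seq_id,
                "target_start": start,
                "target_end": end,
                "insertion_pos": o.insertion[0] if o.insertion else "",
                "insertion_seq": o.insertion[1] if o.insertion else "",
                "seed": o.seed if o.seed is not None else "",
                "gc_percent": round(o.gc_percent, 2),
                "tm_wallace": o.tm_wallace,
                "wobble_label": wobble_label,
            }
        )
    return pd.DataFrame(rows)


def write_oligos_tsv(oligos, path) -> None:
    oligos_to_frame(oligos).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# run configuration
# ----------------------------------------------------------------------

@dataclass
class RunConfig:
    """Flat, fully serializable run configuration; CLI flags override it."""

    engine: str = "nn"
    parameter_path: str = ""
    window: int = 6
    scaling: str = "minmax"
    percentile: float = 90.0
    max_elements: int = 3
    merge_gap: int | None = None
    categories: tuple = ("SENSE", "ANTISENSE")
    chemistry: str = "DNA"
    insertion_len: int = 3
    max_run: int = 7
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["categories"] = list(self.categories)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "categories" in d and d["categories"] is not None:
            d["categories"] = tuple(d["categories"])
        return cls(**d)

    def merged(self, **overrides) -> "RunConfig":
        d = asdict(self)
        d.update({k: v for k, v in overrides.items() if v is not None})
        if isinstance(d.get("categories"), list):
            d["categories"] = tuple(d["categories"])
        return RunConfig(**d)
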