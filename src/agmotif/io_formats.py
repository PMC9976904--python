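"""Readers/writers for the formats the pipeline touches, plus configuration.

Formats
-------
* transcript FASTA (DNA alphabet; ``U`` is normalised to ``T`` on input),
* a region-annotation TSV with columns ``transcript_id, gene_id, len_5utr,
  len_cds, len_3utr, abundance``,
* "react" files: the two-line per-record dialect used by Structure-seq
  tooling — line 1 the transcript id, line 2 tab-separated per-nucleotide
  reactivities with a literal ``NA`` at undefined (G/T) positions,
* header-carrying TSV tables for TMT time courses, enzymology curves and
  all results,
* a flat YAML configuration file.

All coordinates written to output tables are 0-based, half-open.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger(__name__)

REGIONS = ("5UTR", "CDS", "3UTR")

#: default analysis parameters; every threshold of the pipelines is named here.
DEFAULT_CONFIG: dict = {
    "window_offsets": (31, 50),       # nt from the motif edge, inclusive
    "window_len_random": 20,          # nt, random sliding-window "motifs"
    "random_step": 10,                # nt, sliding-window step
    "motif_length": 10,               # nt, R10 / GC5 motif length
    "composition_cap": 7,             # max count of any single base in a motif
    "min_edge_distance": 50,          # nt from region boundary / transcript end
    "min_5utr_len": 100,              # retained transcripts need len_5utr > this
    "min_defined": 5,                 # min defined A/C positions per window
    "min_coverage": 0.0,              # reactivity coverage filter (pass-through)
    "min_five_prime_coverage": 0.0,
    "regions": list(REGIONS),
    "p_cut_fit": 0.1,                 # F-test filter on the rate slope
    "fdr_dependent": 0.1,             # FDR below -> dependent
    "fdr_independent": 0.7,           # FDR above -> independent
    "peptide_combine": "sum",         # peptide -> protein operator
    "difference_test": "z",           # z-test on slope SEs (or "welch")
    "seed": 0,
}


class ValidationError(ValueError):
    """Raised when an input file or configuration fails validation."""


@dataclass
class TranscriptModel:
    """An annotated transcript: sequence, region lengths and abundance.

    The three region lengths partition the sequence: ``len_5utr + len_cds +
    len_3utr == len(sequence)``.  The alphabet is DNA ({A,C,G,T}); purine
    means {A,G}.
    """

    transcript_id: str
    gene_id: str
    sequence: str
    len_5utr: int
    len_cds: int
    len_3utr: int
    abundance: float = 0.0

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence, self.transcript_id)
        for name in ("len_5utr", "len_cds", "len_3utr"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{self.transcript_id}: {name} is negative")
        if self.len_5utr + self.len_cds + self.len_3utr != len(self.sequence):
            raise ValidationError(
                f"{self.transcript_id}: region lengths "
                f"{self.len_5utr}+{self.len_cds}+{self.len_3utr} do not sum to "
                f"sequence length {len(self.sequence)}"
            )
        if self.abundance < 0:
            raise ValidationError(f"{self.transcript_id}: negative abundance")

    def __len__(self) -> int:
        return len(self.sequence)

    def region_bounds(self, region: str) -> tuple[int, int]:
        """0-based half-open bounds of a region on the transcript."""
        if region == "5UTR":
            return 0, self.len_5utr
        if region == "CDS":
            return self.len_5utr, self.len_5utr + self.len_cds
        if region == "3UTR":
            return self.len_5utr + self.len_cds, len(self.sequence)
        raise ValidationError(f"unknown region {region!r}")

    def region_of(self, position: int) -> str:
        for region in REGIONS:
            lo, hi = self.region_bounds(region)
            if lo <= position < hi:
                return region
        raise ValidationError(f"{self.transcript_id}: position {position} out of range")


@dataclass
class ReactivityProfile:
    """Per-nucleotide DMS reactivity for one transcript and condition.

    ``values`` has one entry per nucleotide; positions whose base is G or T
    (DMS probes only unpaired A/C) carry NaN as the explicit undefined
    marker.  Defined values are non-negative.
    """

    transcript_id: str
    condition: str = "control"
    values: np.ndarray = field(default_factory=lambda: np.empty(0))
    coverage: float = 0.0
    five_prime_coverage: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        defined = self.values[np.isfinite(self.values)]
        if (defined < 0).any():
            raise ValidationError(
                f"{self.transcript_id}: negative reactivity value"
            )

    def __len__(self) -> int:
        return len(self.values)

    def validate_against(self, transcript: TranscriptModel) -> None:
        """Check length and that NaN sits exactly at non-A/C positions."""
        if len(self.values) != len(transcript):
            raise ValidationError(
                f"{self.transcript_id}: profile length {len(self.values)} != "
                f"transcript length {len(transcript)}"
            )
        bases = np.frombuffer(transcript.sequence.encode(), dtype="S1")
        ac = (bases == b"A") | (bases == b"C")
        if np.isfinite(self.values[~ac]).any():
            raise ValidationError(
                f"{self.transcript_id}: defined reactivity at a G/T position"
            )


def normalize_sequence(seq: str, seq_id: str = "?") -> str:
    """Uppercase and map U->T; reject anything outside {A,C,G,T}."""
    seq = seq.upper().replace("U", "T")
    for pos, base in enumerate(seq):
        if base not in "ACGT":
            raise ValidationError(
                f"record {seq_id!r}: illegal character {base!r} at position {pos}"
            )
    return seq


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, sequence) pairs, preserving order.

    Sequences are uppercased with U normalised to T.  Duplicate ids, empty
    sequences and characters outside {A,C,G,T,U} are errors.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise ValidationError(f"record {rec.id!r}: empty sequence")
        records.append((rec.id, normalize_sequence(seq, rec.id)))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n{seq}\n")


def read_react(path: str | Path) -> dict[str, np.ndarray]:
    """Read a react file (two lines per record) into id -> value arrays.

    ``NA`` tokens become NaN.  Non-numeric tokens raise a ValidationError
    naming the line number.
    """
    profiles: dict[str, np.ndarray] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 2 != 0:
        raise ValidationError(f"{path}: odd number of lines in react file")
    for i in range(0, len(lines), 2):
        rec_id = lines[i].strip()
        if rec_id.startswith(">"):
            rec_id = rec_id[1:]
        if rec_id in profiles:
            raise ValidationError(f"{path}: duplicate react record {rec_id!r}")
        tokens = lines[i + 1].split("\t")
        values = np.empty(len(tokens))
        for j, tok in enumerate(tokens):
            if tok == "NA":
                values[j] = np.nan
            else:
                try:
                    values[j] = float(tok)
                except ValueError:
                    raise ValidationError(
                        f"{path}: line {i + 2}: non-numeric token {tok!r}"
                    ) from None
        profiles[rec_id] = values
    return profiles


def write_react(profiles: Mapping[str, np.ndarray | ReactivityProfile],
                path: str | Path) -> None:
    """Write profiles in the two-line react dialect (NaN -> ``NA``)."""
    with open(path, "w") as fh:
        for rec_id, values in profiles.items():
            if isinstance(values, ReactivityProfile):
                values = values.values
            tokens = [
                "NA" if not math.isfinite(v) else repr(float(v))
                for v in np.asarray(values, dtype=float)
            ]
            fh.write(f"{rec_id}\n" + "\t".join(tokens) + "\n")


REGION_TABLE_COLUMNS = ["transcript_id", "gene_id", "len_5utr", "len_cds",
                        "len_3utr", "abundance"]
TMT_TABLE_COLUMNS = ["protein_id", "condition", "time_h", "replicate",
                     "intensity_light", "intensity_heavy"]
CURVE_TABLE_COLUMNS = ["time", "signal"]


def read_table(path: str | Path, required: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a header-carrying TSV; verify required columns are present."""
    df = pd.read_csv(path, sep="\t")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"{path}: missing required column(s) {missing}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_transcripts(fasta_path: str | Path,
                     regions_path: str | Path) -> list[TranscriptModel]:
    """Combine a FASTA and a region TSV into TranscriptModel objects."""
    seqs = dict(read_fasta(fasta_path))
    regions = read_table(regions_path, REGION_TABLE_COLUMNS)
    transcripts = []
    for row in regions.itertuples(index=False):
        if row.transcript_id not in seqs:
            raise ValidationError(
                f"{row.transcript_id}: in region table but not in FASTA"
            )
        transcripts.append(TranscriptModel(
            transcript_id=row.transcript_id,
            gene_id=row.gene_id,
            sequence=seqs[row.transcript_id],
            len_5utr=int(row.len_5utr),
            len_cds=int(row.len_cds),
            len_3utr=int(row.len_3utr),
            abundance=float(row.abundance),
        ))
    return transcripts


def load_config(path: str | Path | None = None,
                overrides: Mapping | None = None) -> dict:
    """Load a YAML config, merge with defaults and validate.

    Missing keys take their default value (logged); unknown keys and invalid
    values raise :class:`ValidationError`.
    """
    config = dict(DEFAULT_CONFIG)
    supplied: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        supplied.update(loaded)
    if overrides:
        supplied.update(overrides)
    unknown = set(supplied) - set(config)
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
    for key in config:
        if key in supplied:
            config[key] = supplied[key]
        else:
            logger.info("config: %s not supplied, using default %r",
                        key, config[key])
    _validate_config(config)
    return config


def _validate_config(config: Mapping) -> None:
    lo, hi = config["window_offsets"]
    if lo < 0 or hi < lo:
        raise ValidationError(f"invalid window_offsets {config['window_offsets']!r}")
    for key in ("motif_length", "window_len_random", "random_step"):
        if config[key] < 1:
            raise ValidationError(f"{key} must be >= 1")
    for key in ("composition_cap", "min_edge_distance", "min_5utr_len",
                "min_defined"):
        if config[key] < 0:
            raise ValidationError(f"{key} must be non-negative")
    for key in ("p_cut_fit", "fdr_dependent", "fdr_independent"):
        if not 0 <= config[key] <= 1:
            raise ValidationError(f"{key} must lie in [0,1]")
    bad = set(config["regions"]) - set(REGIONS)
    if bad:
        raise ValidationError(f"unknown region(s) in config: {sorted(bad)}")
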