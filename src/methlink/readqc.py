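"""Raw-read preprocessing: trim to a maximum length and keep only reads
whose 5' end carries an enzyme digestion signature.

The default signatures are the bisulfite-space MspI ends (CGG methylated,
TGG converted) and TaqI ends (CGA, TGA).  Matching is exact-prefix on
read 1; input and output are gzip-transparent FASTQ.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

from Bio.SeqIO.QualityIO import FastqGeneralIterator

DEFAULT_SIGNATURES = frozenset({"CGG", "TGG", "CGA", "TGA"})
DEFAULT_MAX_LEN = 50


@dataclass(frozen=True)
class ReadFilterStats:
    n_input: int
    n_retained: int
    n_trimmed: int

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.n_input if self.n_input else 0.0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_trimmed": self.n_trimmed,
            "retained_fraction": self.retained_fraction,
        }


def _open(path, mode):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def filter_digested_reads(
    fastq_in,
    fastq_out,
    signatures=DEFAULT_SIGNATURES,
    max_len: int = DEFAULT_MAX_LEN,
) -> ReadFilterStats:
    """Retain reads whose sequence starts with any signature, truncating
    sequence and quality to ``max_len``; order is preserved."""
    signatures = {s.upper() for s in signatures}
    if not signatures:
        raise ValueError("signature set must be non-empty")
    n_input = n_retained = n_trimmed = 0
    with _open(fastq_in, "r") as ih, _open(fastq_out, "w") as oh:
        try:
            for title, seq, qual in FastqGeneralIterator(ih):
                n_input += 1
                if not any(seq.upper().startswith(s) for s in signatures):
                    continue
                n_retained += 1
                if len(seq) > max_len:
                    n_trimmed += 1
                    seq, qual = seq[:max_len], qual[:max_len]
                oh.write(f"@{title}\n{seq}\n+\n{qual}\n")
        except ValueError as err:
            raise ValueError(
                f"malformed FASTQ near record {n_input + 1}: {err}"
            ) from err
    return ReadFilterStats(n_input, n_retained, n_trimmed)
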