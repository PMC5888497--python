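"""Guide RNA records and sequence helpers."""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .errors import ConfigurationError
from .intervals import Interval

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_PAM_RE = re.compile(r"^[ACGT]GG$")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GuideRNA:
    """A single gRNA: 20-nt protospacer, NGG PAM and optional genomic site.

    ``seed5`` and ``seed11`` are the PAM-proximal 5 and 11 nt of the
    protospacer, the portions whose base pairing dominates off-target
    binding.
    """

    name: str
    protospacer: str
    pam: str
    chrom: Optional[str] = None
    start: Optional[int] = None  # protospacer interval, 0-based half-open
    end: Optional[int] = None
    strand: str = "."

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise ConfigurationError(
                f"guide {self.name}: protospacer must be 20 nt, "
                f"got {len(self.protospacer)}"
            )
        if not _PAM_RE.match(self.pam):
            raise ConfigurationError(
                f"guide {self.name}: PAM {self.pam!r} does not match NGG"
            )

    @property
    def seed5(self) -> str:
        return self.protospacer[-5:]

    @property
    def seed11(self) -> str:
        return self.protospacer[-11:]

    @property
    def has_site(self) -> bool:
        return self.chrom is not None and self.start is not None and self.end is not None

    def site(self) -> Interval:
        if not self.has_site:
            raise ConfigurationError(f"guide {self.name} has no genomic site")
        return Interval(
            self.chrom, self.start, self.end, name=self.name, strand=self.strand
        )
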