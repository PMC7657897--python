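"""In-silico PCR: predict the product a primer pair would amplify.

The forward primer anneals to the template as written (5'->3'); the
reverse primer anneals to the opposite strand, so its binding site on the
given template is the reverse complement of the primer, downstream of the
forward site. The amplicon spans both primer footprints inclusively —
the standard PCR product definition, under which the study primer pair
yields its 399 bp CPS III product.

The 3'-terminal base of each primer must match the template even when
internal mismatches are tolerated: polymerase extension requires a
paired 3' end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from cpscan.io_formats import SeqRecord
from cpscan.motif_scan import revcomp


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse primers, both written 5'->3'."""

    forward: str
    reverse: str
    label: str = "pair"

    def __post_init__(self) -> None:
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            if len(p) < 10:
                raise ValueError(f"{name} primer shorter than 10 nt")
            bad = set(p.upper()) - set("ACGT")
            if bad:
                raise ValueError(f"{name} primer contains non-ACGT characters {sorted(bad)}")
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product.

    1-based inclusive template span from the 5' end of the forward site to
    the template position complementary to the 5' end of the reverse
    primer; the length therefore includes both primer footprints.
    """

    template_id: str
    start: int
    end: int
    fwd_mismatches: int
    rev_mismatches: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _site_hits(template: str, site: str, max_mismatches: int, anchor_3prime: str
               ) -> list[tuple[int, int]]:
    """0-based start positions + mismatch counts of substitution-only site matches.

    ``anchor_3prime`` is "last" when the primer's 3' end is the last base
    of the site (forward primer) and "first" when it is the first base
    (reverse-complemented reverse primer).
    """
    m = len(site)
    hits = []
    for i in range(len(template) - m + 1):
        window = template[i : i + m]
        anchor = m - 1 if anchor_3prime == "last" else 0
        if window[anchor] != site[anchor]:
            continue
        mm = sum(1 for a, b in zip(window, site) if a != b)
        if mm <= max_mismatches:
            hits.append((i, mm))
    return hits


def find_amplicons(template: SeqRecord, primers: PrimerPair, max_mismatches: int = 0,
                   max_product_length: Optional[int] = None) -> list[Amplicon]:
    """All products formed by a forward site and a downstream reverse site.

    Every combination is reported (no preferred product), sorted by start
    then length. Returns an empty list when either site is absent.
    """
    seq = template.residues
    if not seq:
        raise ValueError("empty template")
    fwd_sites = _site_hits(seq, primers.forward, max_mismatches, "last")
    rev_sites = _site_hits(seq, revcomp(primers.reverse), max_mismatches, "first")
    min_len = len(primers.forward) + len(primers.reverse)
    out = []
    for fs, fmm in fwd_sites:
        for rs, rmm in rev_sites:
            start = fs + 1
            end = rs + len(primers.reverse)  # 1-based inclusive end of reverse footprint
            length = end - start + 1
            if length < min_len:
                continue
            if max_product_length is not None and length > max_product_length:
                continue
            out.append(Amplicon(template_id=template.id, start=start, end=end,
                                fwd_mismatches=fmm, rev_mismatches=rmm))
    out.sort(key=lambda a: (a.start, a.length))
    return out
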