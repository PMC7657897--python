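"""Printed reference inputs of the Alcolapia CPS III study system.

These short sequences are the published comparison fragments and primer
pair the pipeline was built around; they double as worked-example inputs
and acceptance fixtures.
"""

from __future__ import annotations

from cpscan.insilico_pcr import PrimerPair
from cpscan.io_formats import SeqRecord
from cpscan.motif_scan import PromoterRegion

# 31-nt upstream fragments around the candidate paired MyoD E-box,
# located 940-970 bases upstream of the CPS III transcription start site.
# A. alcalica carries two exact CAG(G/C)TG motifs separated by 19 bases;
# O. niloticus differs by a single substitution that degrades the distal
# motif to CAGGTT, leaving one exact motif plus a near-miss.
ALCALICA_PAIRED_EBOX = "CAGGTGACTGTGATTATATAGTTCACAGGTG"
NILOTICUS_EBOX_FRAGMENT = "CAGGTGACTGTGATTATATAGTTCACAGGTT"

# RT-PCR primer pair for CPS III expression profiling; amplifies a 399 bp
# product from the A. alcalica CPS III coding sequence.
CPS3_PRIMERS = PrimerPair(
    forward="CAGTGGGAGGTCAGATTGC",
    reverse="CTCACAGCGAAGCACAGGG",
    label="CPSIII_RTPCR",
)

# Expected product length of the pair above.
CPS3_PRODUCT_LENGTH = 399

# Upstream-distance interval of the paired E-box (distal, proximal edges).
PAIRED_EBOX_UPSTREAM_INTERVAL = (970, 940)

# Length of the upstream windows surveyed per species.
UPSTREAM_WINDOW_LENGTH = 3500


def alcalica_fragment_region() -> PromoterRegion:
    return PromoterRegion(
        record=SeqRecord(id="A_alcalica_frag", residues=ALCALICA_PAIRED_EBOX, alphabet="dna"),
        species="A. alcalica",
    )


def niloticus_fragment_region() -> PromoterRegion:
    return PromoterRegion(
        record=SeqRecord(id="O_niloticus_frag", residues=NILOTICUS_EBOX_FRAGMENT, alphabet="dna"),
        species="O. niloticus",
    )
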