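from __future__ import annotations

import importlib.resources

import pytest

from cpscan.cps_classify import DiagnosticSpec, DiagnosticResidue
from cpscan.io_formats import SeqRecord
from cpscan import study_inputs


@pytest.fixture
def alcalica_region():
    return study_inputs.alcalica_fragment_region()


@pytest.fixture
def niloticus_region():
    return study_inputs.niloticus_fragment_region()


@pytest.fixture
def primers():
    return study_inputs.CPS3_PRIMERS


@pytest.fixture
def template_spec_path():
    return str(importlib.resources.files("cpscan") / "data" / "diagnostic_spec_template.yaml")


@pytest.fixture
def small_spec():
    """A compact diagnostic spec for a short synthetic reference."""
    return DiagnosticSpec(
        ref_id="ref",
        triad=[
            DiagnosticResidue("Cys", 3, "C"),
            DiagnosticResidue("His", 7, "H"),
            DiagnosticResidue("Glu", 9, "E"),
        ],
        gln_binding=[
            DiagnosticResidue("Gln1", 12, "S"),
            DiagnosticResidue("Gln2", 15, "N"),
        ],
    )


@pytest.fixture
def small_ref():
    #            123456789012345678
    return SeqRecord(id="ref", residues="MKCLVAHGEKASMWNTRQ", alphabet="protein")
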