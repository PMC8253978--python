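"""Versioned plain-text (JSON) serialization of biomarker ensembles."""

from __future__ import annotations

import json
from pathlib import Path

from .classifier import Biomarker, ClassifierEnsemble
from .pairs import DirectedGenePair

__all__ = ["write_biomarker", "read_biomarker", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1


def write_biomarker(ensemble: ClassifierEnsemble, path) -> None:
    """Write an ensemble as a versioned JSON document."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "application_order": list(ensemble.application_order),
        "biomarkers": {
            subtype: {
                "vote_rule": bm.vote_rule,
                "pairs": [[p.gene_hi, p.gene_lo] for p in bm.pairs],
            }
            for subtype, bm in ensemble.biomarkers.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_biomarker(path) -> ClassifierEnsemble:
    """Read an ensemble written by :func:`write_biomarker`.

    Unknown schema versions and structurally invalid documents raise.
    """
    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"unknown biomarker schema version {version!r}; "
                         f"this build reads version {SCHEMA_VERSION}")
    biomarkers = {
        subtype: Biomarker(
            subtype=subtype,
            pairs=[DirectedGenePair(hi, lo) for hi, lo in spec["pairs"]],
            vote_rule=spec.get("vote_rule", "strict-majority"),
        )
        for subtype, spec in doc["biomarkers"].items()
    }
    return ClassifierEnsemble(biomarkers=biomarkers,
                              application_order=list(doc["application_order"]))
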