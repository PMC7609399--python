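"""Access to the bundled labelled reference panels.

Both panels are synthetic stand-ins (random sequences with field-style
labels) regenerable with ``scripts/make_panels.py``; they make no claim
to biological homology.  The RdRp panel maps protein ids to RNA-virus
family labels; the SSU panel maps rRNA reference ids to taxonomic class
labels.
"""

from __future__ import annotations

from importlib.resources import files

from Bio import SeqIO


def _load(name: str, tag: str) -> tuple[dict[str, str], dict[str, str]]:
    path = files("segvirome.data").joinpath(name)
    seqs: dict[str, str] = {}
    labels: dict[str, str] = {}
    with path.open() as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seqs[rec.id] = str(rec.seq).upper()
            label = rec.id
            for field in rec.description.split():
                if field.startswith(tag + "="):
                    label = field.split("=", 1)[1]
            labels[rec.id] = label
    return seqs, labels


def load_rdrp_panel() -> tuple[dict[str, str], dict[str, str]]:
    """(protein sequences by id, family label by id)."""
    return _load("synthetic_rdrp_panel.fasta", "family")


def load_ssu_panel() -> tuple[dict[str, str], dict[str, str]]:
    """(rRNA sequences by id, class label by id)."""
    return _load("synthetic_ssu_panel.fasta", "class")
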