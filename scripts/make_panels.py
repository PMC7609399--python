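"""Regenerate the bundled synthetic reference panels.

The shipped panels are synthetic stand-ins: random protein sequences
labelled with RNA-virus family names, and random nucleotide sequences
labelled with SSU rRNA class names.  They carry no homology to real
RdRp or rRNA sequences; they exist so that detection, labelling and
profiling logic can be exercised and verified by parameter recovery.
Run from the repository root:

    python scripts/make_panels.py
"""

from pathlib import Path

import numpy as np

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
NT = np.array(list("ACGT"))

RDRP_FAMILIES = [
    ("Partitiviridae", 4),
    ("Totiviridae", 1),
    ("Narnaviridae", 1),
    ("Chrysoviridae", 1),
    ("Endornaviridae", 1),
    ("Amalgaviridae", 1),
    ("Picobirnaviridae", 1),
    ("Megabirnaviridae", 1),
    ("Botybirnaviridae", 1),
    ("Hypoviridae", 1),
    ("Polymycoviridae", 1),
    ("Gammaflexviridae", 1),
    ("unclassified", 1),
]

SSU_CLASSES = [
    ("Lecanoromycetes", 1),
    ("Trebouxiophyceae", 2),
    ("Sordariomycetes", 1),
    ("Dothideomycetes", 1),
    ("Eurotiomycetes", 1),
    ("Agaricomycetes", 1),
    ("Tremellomycetes", 1),
    ("Bryopsida", 1),
]


def wrap(seq: str, width: int = 70) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def main() -> None:
    out_dir = Path(__file__).resolve().parents[1] / "src" / "segvirome" / "data"
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(561344)

    lines = []
    for family, n in RDRP_FAMILIES:
        for i in range(1, n + 1):
            length = int(rng.integers(505, 531))
            prot = "M" + "".join(rng.choice(AA, size=length - 1))
            lines.append(f">RdRp_{family}_{i} family={family} synthetic=true")
            lines.append(wrap(prot))
    (out_dir / "synthetic_rdrp_panel.fasta").write_text("\n".join(lines) + "\n")

    lines = []
    for cls, n in SSU_CLASSES:
        for i in range(1, n + 1):
            seq = "".join(rng.choice(NT, size=1200))
            lines.append(f">SSU_{cls}_{i} class={cls} synthetic=true")
            lines.append(wrap(seq))
    (out_dir / "synthetic_ssu_panel.fasta").write_text("\n".join(lines) + "\n")


if __name__ == "__main__":
    main()
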