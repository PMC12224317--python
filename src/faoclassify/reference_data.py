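"""Published second-order rate constants for characterized FAO enzymes.

Each entry gives the measured bimolecular constants (M^-1 s^-1) for flavin
reoxidation by O2 and, where a genome-associated cytochrome c exists, by
that CytC (fast and slow phase).  ``expected_call`` is the verdict the
measurements support under the default classifier thresholds; the clade-1
enzymes and the slow no-CytC enzymes are deliberately ``indeterminate``
(solution kinetics with a membrane-bound c4 cytochrome, or product-free O2
rates that product binding is known to accelerate, do not settle the
question).
"""

from __future__ import annotations

from .oxidant_classify import RateConstantSet

__all__ = ["REFERENCE_ENZYMES", "reference_rate_constants", "reference_frame"]

# (enzyme, clade, k_ox_o2, k_ox1_cytc, k_ox2_cytc, signal_peptide,
#  adjacent_cytc, expected_call)
REFERENCE_ENZYMES: list[dict] = [
    # clade 2
    dict(enzyme="T. dinghuensis", clade=2, k_ox_o2=380.0, k_ox1_cytc=2.4e5,
         k_ox2_cytc=3.5e4, signal=True, cytc=True, expected="dehydrogenase"),
    dict(enzyme="B. anthina", clade=2, k_ox_o2=4.8e3, k_ox1_cytc=2.9e4,
         k_ox2_cytc=1.1e3, signal=True, cytc=True, expected="dual"),
    dict(enzyme="E. alkalisoli", clade=2, k_ox_o2=670.0, k_ox1_cytc=3.4e5,
         k_ox2_cytc=1.1e4, signal=True, cytc=True, expected="dehydrogenase"),
    dict(enzyme="B. cepacia", clade=2, k_ox_o2=1.9e3, k_ox1_cytc=None,
         k_ox2_cytc=None, signal=False, cytc=False, expected="indeterminate"),
    dict(enzyme="R. sordida", clade=2, k_ox_o2=6.1e3, k_ox1_cytc=None,
         k_ox2_cytc=None, signal=False, cytc=False, expected="indeterminate"),
    dict(enzyme="Janthinobacterium sp. PC23-8", clade=2, k_ox_o2=1.2e4,
         k_ox1_cytc=None, k_ox2_cytc=None, signal=False, cytc=False,
         expected="oxidase"),
    dict(enzyme="P. reinekei", clade=2, k_ox_o2=2.6e4, k_ox1_cytc=None,
         k_ox2_cytc=None, signal=True, cytc=False, expected="oxidase"),
    dict(enzyme="P. putida OR45a", clade=2, k_ox_o2=1.6e4, k_ox1_cytc=None,
         k_ox2_cytc=None, signal=False, cytc=False, expected="oxidase"),
    # clade 3
    dict(enzyme="Pseudomonas sp. GL-RE-19", clade=3, k_ox_o2=24.0,
         k_ox1_cytc=3.5e5, k_ox2_cytc=6.8e4, signal=True, cytc=True,
         expected="dehydrogenase"),
    dict(enzyme="K. lipolytica", clade=3, k_ox_o2=1.8e3, k_ox1_cytc=1.0e6,
         k_ox2_cytc=1.3e5, signal=True, cytc=True, expected="dehydrogenase"),
    dict(enzyme="M. nitratireducens", clade=3, k_ox_o2=390.0, k_ox1_cytc=4.3e5,
         k_ox2_cytc=3.9e4, signal=True, cytc=True, expected="dehydrogenase"),
    dict(enzyme="P. taiwanensis", clade=3, k_ox_o2=6.6e3, k_ox1_cytc=2.8e6,
         k_ox2_cytc=3.7e5, signal=True, cytc=True, expected="dehydrogenase"),
    dict(enzyme="P. nitroreducens", clade=3, k_ox_o2=1.9e3, k_ox1_cytc=7.2e5,
         k_ox2_cytc=2.1e4, signal=True, cytc=True, expected="dehydrogenase"),
    dict(enzyme="T. aromatica", clade=3, k_ox_o2=1.6e3, k_ox1_cytc=4.7e5,
         k_ox2_cytc=1.1e5, signal=True, cytc=True, expected="dehydrogenase"),
    dict(enzyme="NicA2 (P. putida S16)", clade=3, k_ox_o2=27.0, k_ox1_cytc=1.0e6,
         k_ox2_cytc=2.7e5, signal=True, cytc=True, expected="dehydrogenase"),
    dict(enzyme="Pnao (P. putida S16)", clade=3, k_ox_o2=600.0, k_ox1_cytc=1.4e5,
         k_ox2_cytc=3.2e4, signal=True, cytc=True, expected="dehydrogenase"),
    dict(enzyme="NctB (Shinella sp. HZN7)", clade=3, k_ox_o2=1.9e3,
         k_ox1_cytc=None, k_ox2_cytc=None, signal=False, cytc=False,
         expected="indeterminate"),
    dict(enzyme="A. digitatis", clade=3, k_ox_o2=1.6e4, k_ox1_cytc=None,
         k_ox2_cytc=None, signal=False, cytc=False, expected="oxidase"),
    dict(enzyme="Sphingopyxis sp. YR83", clade=3, k_ox_o2=2.7e3,
         k_ox1_cytc=None, k_ox2_cytc=None, signal=True, cytc=False,
         expected="indeterminate"),
    dict(enzyme="Streptomyces sp. CJ13", clade=3, k_ox_o2=5.1e4,
         k_ox1_cytc=None, k_ox2_cytc=None, signal=False, cytc=False,
         expected="oxidase"),
    dict(enzyme="Synechoccocus sp. UW140", clade=3, k_ox_o2=5.6e4,
         k_ox1_cytc=None, k_ox2_cytc=None, signal=False, cytc=False,
         expected="oxidase"),
    dict(enzyme="Erythrobacter sp. 1414", clade=3, k_ox_o2=470.0,
         k_ox1_cytc=None, k_ox2_cytc=None, signal=True, cytc=False,
         expected="indeterminate"),
    dict(enzyme="R. tatauoinensis", clade=3, k_ox_o2=3.1e3, k_ox1_cytc=None,
         k_ox2_cytc=None, signal=True, cytc=False, expected="indeterminate"),
    # clade 1 (c4-type, membrane-bound cytochromes; solution rates modest)
    dict(enzyme="B. metallica", clade=1, k_ox_o2=320.0, k_ox1_cytc=990.0,
         k_ox2_cytc=None, signal=True, cytc=True, expected="indeterminate"),
    dict(enzyme="P. aeruginosa", clade=1, k_ox_o2=160.0, k_ox1_cytc=290.0,
         k_ox2_cytc=None, signal=True, cytc=True, expected="indeterminate"),
    dict(enzyme="B. stagnalis", clade=1, k_ox_o2=590.0, k_ox1_cytc=2.7e3,
         k_ox2_cytc=210.0, signal=True, cytc=True, expected="indeterminate"),
    dict(enzyme="P. otitidis", clade=1, k_ox_o2=4.5e3, k_ox1_cytc=None,
         k_ox2_cytc=None, signal=True, cytc=False, expected="indeterminate"),
]


def reference_rate_constants() -> list[tuple[RateConstantSet, str, int]]:
    """(RateConstantSet, expected verdict, clade) for every reference enzyme."""
    out = []
    for row in REFERENCE_ENZYMES:
        rc = RateConstantSet(
            enzyme=row["enzyme"],
            k_ox_o2=row["k_ox_o2"],
            k_ox1_cytc=row["k_ox1_cytc"],
            k_ox2_cytc=row["k_ox2_cytc"],
            has_signal_peptide=row["signal"],
            has_adjacent_cytc=row["cytc"],
        )
        out.append((rc, row["expected"], row["clade"]))
    return out


def reference_frame():
    """The reference constants as a pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame(REFERENCE_ENZYMES)
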