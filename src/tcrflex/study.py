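"""Published inputs of the unbound-TCR flexibility study this package
re-implements.

These are transcribed data tables — deposited PDB accessions, author-numbered
CDR/framework loop ranges, crystallographic resolution limits, and the
published per-loop apex amplitudes — usable both as pipeline inputs (loop
definitions, accession lists) and as reference values when validating report
arithmetic.  Amplitudes are in Å; resolution limits in Å.
"""

from __future__ import annotations

from .structure_model import LoopDefinition

#: Deposited accessions per T-cell receptor (unbound structures).
ACCESSIONS: dict[str, list[str]] = {
    "F11": ["6FR9", "6FRA", "6EH7", "6FRB", "6EH6", "6FRC",
            "6FUM", "6FUN", "6FUO", "6FUP", "6FUQ", "6FUR"],
    "HA1.7": ["6FR6", "6FR7", "6FR8", "6EH8", "6EH9"],
    "003": ["6FR3", "6FR4", "6EH4", "6FR5", "6EH5"],
}

#: Loop ranges (author numbering) per receptor; alpha-chain loops first.
#: Chain ids are placeholders "alpha"/"beta" to be mapped onto the first and
#: second protein chains of a deposited file.
LOOP_RANGES: dict[str, dict[str, tuple[str, int, int]]] = {
    "F11": {
        "CDR1a": ("alpha", 25, 30), "CDR2a": ("alpha", 49, 54),
        "Fwa": ("alpha", 66, 72), "CDR3a": ("alpha", 93, 98),
        "CDR1b": ("beta", 23, 29), "CDR2b": ("beta", 48, 53),
        "Fwb": ("beta", 66, 72), "CDR3b": ("beta", 92, 98),
    },
    "HA1.7": {
        "CDR1a": ("alpha", 25, 30), "CDR2a": ("alpha", 49, 54),
        "Fwa": ("alpha", 66, 72), "CDR3a": ("alpha", 93, 101),
        "CDR1b": ("beta", 26, 31), "CDR2b": ("beta", 49, 54),
        "Fwb": ("beta", 69, 74), "CDR3b": ("beta", 96, 102),
    },
    "003": {
        "CDR1a": ("alpha", 27, 34), "CDR2a": ("alpha", 52, 57),
        "Fwa": ("alpha", 68, 74), "CDR3a": ("alpha", 95, 100),
        "CDR1b": ("beta", 27, 32), "CDR2b": ("beta", 50, 55),
        "Fwb": ("beta", 69, 74), "CDR3b": ("beta", 95, 102),
    },
}

#: Published apex amplitudes (Å) per loop and receptor.
PUBLISHED_AMPLITUDES: dict[str, dict[str, float]] = {
    "F11": {"CDR1a": 7.7, "CDR2a": 9.4, "Fwa": 8.4, "CDR3a": 10.6,
            "CDR1b": 8.3, "CDR2b": 6.5, "Fwb": 6.5, "CDR3b": 12.2},
    "HA1.7": {"CDR1a": 8.0, "CDR2a": 6.9, "Fwa": 11.0, "CDR3a": 9.9,
              "CDR1b": 9.0, "CDR2b": 6.9, "Fwb": 6.1, "CDR3b": 14.9},
    "003": {"CDR1a": 6.0, "CDR2a": 6.8, "Fwa": 6.8, "CDR3a": 10.2,
            "CDR1b": 4.4, "CDR2b": 3.0, "Fwb": 4.8, "CDR3b": 9.4},
}

#: Published per-receptor mean apex amplitudes (Å).
PUBLISHED_MEAN_PER_TCR: dict[str, float] = {"F11": 8.7, "HA1.7": 9.0, "003": 6.4}

#: Published per-loop mean apex amplitudes over the three receptors (Å).
PUBLISHED_MEAN_PER_LOOP: dict[str, float] = {
    "CDR1a": 7.2, "CDR2a": 7.7, "Fwa": 8.7, "CDR3a": 10.2,
    "CDR1b": 7.2, "CDR2b": 5.5, "Fwb": 5.8, "CDR3b": 12.2,
}

#: High-resolution diffraction limits (Å) per receptor dataset.
RESOLUTION_LIMITS: dict[str, list[float]] = {
    "F11": [1.62, 1.73, 1.89, 1.75, 1.78, 1.59, 1.76, 1.58, 1.70, 1.72, 1.60, 1.73],
    "HA1.7": [2.98, 2.31, 2.38, 2.51, 2.49],
    "003": [1.35, 1.28, 1.26, 1.37, 1.29],
}

GERMLINE_LOOPS = ["CDR1a", "CDR2a", "Fwa", "CDR1b", "CDR2b", "Fwb"]
CDR3_LOOPS = ["CDR3a", "CDR3b"]


def loop_definitions(tcr: str, alpha_chain: str, beta_chain: str) -> list[LoopDefinition]:
    """Concrete loop definitions for one receptor, mapped onto chain ids."""
    chain_map = {"alpha": alpha_chain, "beta": beta_chain}
    return [
        LoopDefinition(name, chain_map[which], start, end)
        for name, (which, start, end) in LOOP_RANGES[tcr].items()
    ]
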