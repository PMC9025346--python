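"""Read-only reference dataset: the published Chinese hamster (*Cricetulus
griseus*) large-tandem-repeat catalog.

Three tables ship with the package, transcribed cell-for-cell from the
published catalog built over the AFTD (CHO-K1), APMK (chromosome-sorted) and
AMDS whole-genome assemblies:

* ``families`` — 21 TR families with maximum array length, GC %, amount in
  genome %, assembly of maximum content, in-silico chromosomes, and
  repeat-library similarity (B1/ERV/ERV2/Tc1 are transposable elements;
  SAU1.5 is a known satellite, Zn-finger a gene fragment);
* ``cooccurrence`` — which families are shared between which assemblies;
* ``probes`` — the 13 FISH oligos designed from that catalog.

They serve as the desk-scale worked example for probe-family selection and
as fixtures for the probe QC gates.
"""
from __future__ import annotations

import re
from importlib import resources

import pandas as pd

_DATA = resources.files("satfam") / "data" / "cgriseus"


def _read(name: str) -> pd.DataFrame:
    with resources.as_file(_DATA / name) as path:
        return pd.read_csv(path, sep="\t", keep_default_na=False)


def load_family_table() -> pd.DataFrame:
    """The 21-row family catalog, with ``min_monomer`` derived from the
    family-name numeral (names encode the minimum monomer length in bp)."""
    df = _read("families.tsv")
    df["min_monomer"] = [int(re.match(r"(\d+)", n).group(1)) for n in df["name"]]
    df["abundance_percent"] = df["abundance_percent"].astype(float)
    return df


def load_cooccurrence() -> dict[frozenset, list[str]]:
    """Assembly-set -> family names shared by exactly that set."""
    df = _read("cooccurrence.tsv")
    out: dict[frozenset, list[str]] = {}
    for _, row in df.iterrows():
        asms = frozenset(str(row["assemblies"]).split("+"))
        fams = [f.strip() for f in str(row["families"]).split(",") if f.strip()]
        out[asms] = fams
    return out


def cooccurrence_counts() -> dict[str, int]:
    """Family name -> number of assemblies it occurs in (families absent from
    the shared classes are single-assembly)."""
    counts: dict[str, int] = {}
    for asms, fams in load_cooccurrence().items():
        for fam in fams:
            counts[fam] = len(asms)
    return counts


def load_probe_table() -> pd.DataFrame:
    """The 13 published FISH oligo probes (family name + sequence)."""
    return _read("probes.tsv")
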