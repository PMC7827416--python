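"""Homoeolog pair construction from BLAST tabular hits.

A-subgenome gene models aligned against C-subgenome gene models yield a
standard 12-column tabular hit list. Hits are filtered at E-value <= 1e-10
and identity > 90% (strict), then reduced to a one-to-one matching by greedy
best-bitscore sweep with deterministic tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .io import FormatError, HomoeologPairTable

EVALUE_CUTOFF = 1e-10
IDENTITY_CUTOFF = 90.0


@dataclass(frozen=True)
class BlastHit:
    query: str       # A-subgenome gene id
    subject: str     # C-subgenome gene id
    identity_pct: float
    align_len: int
    evalue: float
    bitscore: float


def parse_blast_tab(path: str | Path) -> list[BlastHit]:
    """Parse 12-column BLAST tabular output (outfmt-6 dialect).

    Columns used: 1 query, 2 subject, 3 identity, 4 alignment length,
    11 E-value, 12 bitscore. Any line with a different column count is a
    format error; an empty file yields an empty list.
    """
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            hits.append(
                BlastHit(
                    query=fields[0],
                    subject=fields[1],
                    identity_pct=float(fields[2]),
                    align_len=int(fields[3]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            )
    return hits


def filter_hits(
    hits: list[BlastHit],
    evalue: float = EVALUE_CUTOFF,
    identity: float = IDENTITY_CUTOFF,
) -> list[BlastHit]:
    """Keep hits with E-value <= cutoff and identity strictly above cutoff."""
    return [h for h in hits if h.evalue <= evalue and h.identity_pct > identity]


def build_pairs(hits: list[BlastHit]) -> HomoeologPairTable:
    """Greedy best-hit one-to-one matching of A genes to C genes.

    Hits are swept in order of (bitscore desc, evalue asc, subject asc,
    query asc); a hit is kept when both endpoints are still unmatched.
    The sweep order makes the matching deterministic on any input.
    """
    order = sorted(hits, key=lambda h: (-h.bitscore, h.evalue, h.subject, h.query))
    used_a: set[str] = set()
    used_c: set[str] = set()
    rows = []
    for h in order:
        if h.query in used_a or h.subject in used_c:
            continue
        used_a.add(h.query)
        used_c.add(h.subject)
        rows.append(
            {
                "gene_A": h.query,
                "gene_C": h.subject,
                "identity_pct": h.identity_pct,
                "evalue": h.evalue,
            }
        )
    rows.sort(key=lambda r: (r["gene_A"], r["gene_C"]))
    df = pd.DataFrame(rows, columns=["gene_A", "gene_C", "identity_pct", "evalue"])
    df.insert(0, "pair_id", [f"pair{i + 1:06d}" for i in range(len(df))])
    return HomoeologPairTable(df)


def pairs_from_blast(
    path: str | Path,
    evalue: float = EVALUE_CUTOFF,
    identity: float = IDENTITY_CUTOFF,
) -> HomoeologPairTable:
    return build_pairs(filter_hits(parse_blast_tab(path), evalue, identity))
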