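"""In-silico protease cleavage-site prediction.

Each annotated urinary peptide implies up to two proteolytic events in its
parent protein: the cut that generated its N terminus (between residues
start−1 and start) and the cut that generated its C terminus (between
residues end and end+1); termini coinciding with the protein's own ends are
not cleavage events.  Site context is recorded in Schechter–Berger
nomenclature (P4–P1 before the scissile bond, P1'–P4' after).

Candidate proteases are scored by single-position specificity rules: a rule
matches when the site's P1 residue is in the rule's P1 set or its P1'
residue is in the rule's P1' set.  The shipped default table covers the
serine and metallo proteases commonly proposed for uromodulin C-terminal
processing (hepsin, meprin A subunit α, granzyme A, cathepsin G, MMP-3,
MMP-12, plasmin(ogen), neutrophil elastase) with meprin Aα at medium
confidence and the rest at low confidence.  The residue sets encode
conventional textbook P1/P1' preferences and are curation choices — the
table is plain data and fully user-replaceable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

GENERATES_N = "generates_N_terminus"
GENERATES_C = "generates_C_terminus"

CONFIDENCE_ORDER = {"medium": 0, "low": 1}


@dataclass(frozen=True)
class CleavageSite:
    """A cleavage between residues ``position`` and ``position + 1``."""

    protein: str
    position: int  # 1-based index of the P1 residue
    terminus_role: str
    context: str  # P4 P3 P2 P1 P1' P2' P3' P4', '-' padding at protein ends

    @property
    def p1(self) -> str:
        return self.context[3]

    @property
    def p1_prime(self) -> str:
        return self.context[4]


@dataclass(frozen=True)
class ProteaseRule:
    name: str
    protease_class: str  # "serine" | "metallo"
    p1_residues: frozenset[str]
    p1prime_residues: frozenset[str]
    confidence: str  # "medium" | "low"

    def __post_init__(self) -> None:
        if not self.p1_residues and not self.p1prime_residues:
            raise ValueError(f"rule {self.name!r}: both residue sets empty")
        if self.confidence not in CONFIDENCE_ORDER:
            raise ValueError(f"rule {self.name!r}: unknown confidence {self.confidence!r}")


@dataclass(frozen=True)
class CleavagePrediction:
    site: CleavageSite
    protease: str
    matched_on: str  # "P1" | "P1prime" | "both"
    confidence: str


def _rule(name, cls, p1, p1p, conf) -> ProteaseRule:
    return ProteaseRule(name, cls, frozenset(p1), frozenset(p1p), conf)


#: Default specificity table.  Residue sets are conventional preferences
#: (curation choices), not measured specificities:
#: trypsin-like serine proteases (hepsin, plasmin, granzyme A) cut after K/R;
#: cathepsin G is chymotrypsin-like (after bulky hydrophobics); neutrophil
#: elastase cuts after small aliphatics; the metalloproteases are modelled on
#: the prime side — MMPs prefer hydrophobic P1', meprin Aα acidic/small P1'.
DEFAULT_RULES: tuple[ProteaseRule, ...] = (
    _rule("meprin A subunit alpha", "metallo", "", "DEST", "medium"),
    _rule("hepsin", "serine", "KR", "", "low"),
    _rule("plasminogen", "serine", "KR", "", "low"),
    _rule("granzyme A", "serine", "KR", "", "low"),
    _rule("cathepsin G", "serine", "FYWL", "", "low"),
    _rule("neutrophil elastase", "serine", "AVIT", "", "low"),
    _rule("MMP-3", "metallo", "", "LIVFM", "low"),
    _rule("MMP-12", "metallo", "", "LIVFM", "low"),
)


def extract_cleavage_sites(
    start_pos: int, end_pos: int, parent_sequence: str, protein: str = "?"
) -> list[CleavageSite]:
    """The 0–2 cleavage sites implied by one peptide's coordinates."""
    n = len(parent_sequence)
    if not (1 <= start_pos <= end_pos <= n):
        raise ValueError(
            f"peptide coordinates [{start_pos}, {end_pos}] outside parent "
            f"{protein!r} of length {n}"
        )
    sites = []
    if start_pos > 1:
        sites.append(
            CleavageSite(
                protein=protein,
                position=start_pos - 1,
                terminus_role=GENERATES_N,
                context=_context(parent_sequence, start_pos - 1),
            )
        )
    if end_pos < n:
        sites.append(
            CleavageSite(
                protein=protein,
                position=end_pos,
                terminus_role=GENERATES_C,
                context=_context(parent_sequence, end_pos),
            )
        )
    return sites


def _context(sequence: str, position: int) -> str:
    """P4..P1 (residues position−3..position) and P1'..P4' with '-' padding."""
    out = []
    for idx in range(position - 3, position + 5):
        out.append(sequence[idx - 1] if 1 <= idx <= len(sequence) else "-")
    return "".join(out)


def predict_proteases(
    site: CleavageSite, rules: tuple[ProteaseRule, ...] | list[ProteaseRule] = DEFAULT_RULES
) -> list[CleavagePrediction]:
    """Rules compatible with one site, ordered by confidence tier then name."""
    predictions = []
    for rule in rules:
        hit_p1 = site.p1 in rule.p1_residues
        hit_p1p = site.p1_prime in rule.p1prime_residues
        if not (hit_p1 or hit_p1p):
            continue
        matched_on = "both" if (hit_p1 and hit_p1p) else ("P1" if hit_p1 else "P1prime")
        predictions.append(
            CleavagePrediction(site, rule.name, matched_on, rule.confidence)
        )
    predictions.sort(key=lambda p: (CONFIDENCE_ORDER[p.confidence], p.protease))
    return predictions


def predict_for_study(
    annotations: pd.DataFrame,
    parents: dict[str, str],
    rules: tuple[ProteaseRule, ...] | list[ProteaseRule] = DEFAULT_RULES,
) -> pd.DataFrame:
    """Per-terminus predictions for all annotated peptides, deduplicated by
    (protein, position, terminus role)."""
    seen: set[tuple[str, int, str]] = set()
    rows = []
    for _, ann in annotations.iterrows():
        parent = parents.get(ann.parent_protein)
        if parent is None:
            raise KeyError(f"parent sequence {ann.parent_protein!r} not supplied")
        for site in extract_cleavage_sites(
            int(ann.start_pos), int(ann.end_pos), parent, ann.parent_protein
        ):
            key = (site.protein, site.position, site.terminus_role)
            if key in seen:
                continue
            seen.add(key)
            preds = predict_proteases(site, rules)
            for pred in preds:
                rows.append(
                    {
                        "protein": site.protein,
                        "position": site.position,
                        "terminus_role": site.terminus_role,
                        "context": site.context,
                        "p1": site.p1,
                        "p1_prime": site.p1_prime,
                        "protease": pred.protease,
                        "matched_on": pred.matched_on,
                        "confidence": pred.confidence,
                    }
                )
            if not preds:
                rows.append(
                    {
                        "protein": site.protein,
                        "position": site.position,
                        "terminus_role": site.terminus_role,
                        "context": site.context,
                        "p1": site.p1,
                        "p1_prime": site.p1_prime,
                        "protease": "",
                        "matched_on": "",
                        "confidence": "",
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["protein", "position", "terminus_role", "context", "p1",
                 "p1_prime", "protease", "matched_on", "confidence"],
    )


# ---------------------------------------------------------------------------
# rule-table serialization (TSV: protease  class  p1_residues  p1prime_residues
# confidence; '-' for an empty residue set)


def save_rules(rules, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "protease": [r.name for r in rules],
            "class": [r.protease_class for r in rules],
            "p1_residues": ["".join(sorted(r.p1_residues)) or "-" for r in rules],
            "p1prime_residues": ["".join(sorted(r.p1prime_residues)) or "-" for r in rules],
            "confidence": [r.confidence for r in rules],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_rules(path: str | Path) -> list[ProteaseRule]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("-")
    rules = []
    for _, row in df.iterrows():
        rules.append(
            ProteaseRule(
                name=row["protease"],
                protease_class=row["class"],
                p1_residues=frozenset(row["p1_residues"].replace("-", "")),
                p1prime_residues=frozenset(row["p1prime_residues"].replace("-", "")),
                confidence=row["confidence"],
            )
        )
    return rules
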