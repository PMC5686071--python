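"""Opsin repertoire annotation: family assignment, status, copy counts.

Candidate genes are assigned to an opsin family by a best-hit local
alignment against a labelled reference set (affine gaps, BLOSUM62-style
scores shipped as data).  The normalised score — raw score divided by the
best reference's self-score — replaces database-dependent e-value
thresholds: a family is called iff the normalised score reaches the call
threshold (default 0.3).

Status follows the coding-sequence rules: *pseudogene* if an in-frame stop
occurs strictly before the terminal codon; else *truncated* if an exon is
missing relative to the family's exon model or the CDS carries more than
100 ``N``s; else *complete*.  Only complete genes enter the copy-number
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .io_formats import GeneRecord

FAMILIES = ("LWS", "SWS1", "SWS2", "Rh2", "Exorh", "Rh1")
SUBTYPED_FAMILIES = {"Rh2", "SWS2"}
CALL_THRESHOLD = 0.3
SUBTYPE_MARGIN = 0.02
MAX_N_COUNT = 100  # "more than 100 Ns" => truncated; exactly 100 is fine

# Expected exon counts per family: Exorh keeps the ancestral five-exon
# structure, the retro-duplicated Rh1 is intronless; cone opsins hold the
# canonical vertebrate structures.
DEFAULT_EXON_MODEL = {"Exorh": 5, "Rh1": 1, "LWS": 6, "SWS1": 5, "SWS2": 5, "Rh2": 5}

GAP_OPEN = -11
GAP_EXTEND = -1

_DNA = set("ACGTN")


def load_score_matrix():
    """Shipped BLOSUM62-equivalent substitution table."""
    text = resources.files("opsinevo.data").joinpath("blosum62.tsv").read_text()
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    alphabet = lines[0].lstrip("\t").split("\t")
    mat = substitution_matrices.Array(alphabet="".join(alphabet), dims=2)
    for ln in lines[1:]:
        parts = ln.split("\t")
        a = parts[0]
        for b, v in zip(alphabet, parts[1:]):
            mat[a, b] = float(v)
    return mat


_MATRIX = None


def _matrix():
    global _MATRIX
    if _MATRIX is None:
        _MATRIX = load_score_matrix()
    return _MATRIX


def _aligner(mode: str) -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = mode
    a.substitution_matrix = _matrix()
    a.open_gap_score = GAP_OPEN
    a.extend_gap_score = GAP_EXTEND
    return a


def _as_protein(seq: str) -> str:
    s = seq.strip().upper()
    if s and set(s) <= _DNA:
        # nucleotide input: translate frame 1, stop at first stop codon
        prot = str(Seq(s[: len(s) - len(s) % 3]).translate())
        prot = prot.split("*")[0]
        return prot.replace("J", "X")
    return s


def local_align_score(query: str, reference: str) -> float:
    """Affine-gap Smith--Waterman score (gap of length L costs
    ``|open| + (L-1)|extend|``)."""
    if not query or not reference:
        return 0.0
    return float(_aligner("local").score(query, reference))


@dataclass
class BestHit:
    reference_id: str | None
    score: float
    normalized_score: float


def best_hit_search(
    query: str,
    references: Mapping[str, str],
    call_threshold: float = CALL_THRESHOLD,
) -> BestHit:
    """Best local-alignment hit of a protein (or frame-1 CDS) against a
    labelled reference set.

    Normalised score = raw score / self-score of the best reference, in
    [0, 1] for homologs.  Ties are broken by reference order in the input
    mapping (stable).  A hit below ``call_threshold`` yields no call
    (``reference_id`` None).
    """
    if not references:
        raise ValueError("empty reference set")
    prot = _as_protein(query)
    if not prot:
        raise ValueError("empty query sequence")
    best_id, best_score = None, -np.inf
    for rid, rseq in references.items():
        s = local_align_score(prot, _as_protein(rseq))
        if s > best_score:
            best_id, best_score = rid, s
    self_score = local_align_score(_as_protein(references[best_id]), _as_protein(references[best_id]))
    norm = best_score / self_score if self_score > 0 else 0.0
    if norm < call_threshold:
        return BestHit(None, float(best_score), float(norm))
    return BestHit(best_id, float(best_score), float(norm))


def classify_status(
    record: GeneRecord,
    expected_exons: int | None = None,
) -> str:
    """complete | pseudogene | truncated, per the coding-sequence rules.

    Pseudogene: an in-frame stop strictly before the terminal codon (a
    stop in the final codon position is the terminal stop, not premature).
    Truncated: exon count below the family's expected count, or more than
    100 ``N``s in the CDS.  Otherwise complete.
    """
    cds = record.cds.upper()
    if len(cds) % 3 != 0:
        if expected_exons is None:
            raise ValueError(
                f"{record.gene_id}: CDS length {len(cds)} not divisible by 3 and no exon model"
            )
        # frame broken: fall through to truncation checks on floor codons
    n_codons = len(cds) // 3
    stops = {"TAA", "TAG", "TGA"}
    for i in range(n_codons - 1):  # exclude the terminal codon
        if cds[3 * i : 3 * i + 3] in stops:
            return "pseudogene"
    if expected_exons is not None and len(record.exons) < expected_exons:
        return "truncated"
    if record.n_count > MAX_N_COUNT:
        return "truncated"
    return "complete"


@dataclass
class OpsinCall:
    gene_id: str
    species: str
    family: str | None
    subtype: str | None
    status: str
    best_hit_id: str | None
    score: float
    normalized_score: float
    n_count: int


def annotate_genes(
    records: Iterable[GeneRecord],
    references: Mapping[str, str],
    subtype_references: Mapping[str, Mapping[str, str]] | None = None,
    exon_model: Mapping[str, int] | None = None,
    call_threshold: float = CALL_THRESHOLD,
) -> list[OpsinCall]:
    """Family call + status + optional subtype for every gene record.

    ``references`` map reference id -> protein; the family of a reference
    is its id up to the first underscore (e.g. ``LWS_zebrafish``) or the
    full id.  ``subtype_references`` maps family -> subtype id -> protein.
    """
    exon_model = dict(DEFAULT_EXON_MODEL if exon_model is None else exon_model)
    calls = []
    for rec in records:
        hit = best_hit_search(rec.cds if rec.protein is None else rec.protein,
                              references, call_threshold)
        family = hit.reference_id.split("_")[0] if hit.reference_id else None
        status = classify_status(rec, exon_model.get(family) if family else None)
        call = OpsinCall(
            gene_id=rec.gene_id,
            species=rec.species,
            family=family,
            subtype=None,
            status=status,
            best_hit_id=hit.reference_id,
            score=hit.score,
            normalized_score=hit.normalized_score,
            n_count=rec.n_count,
        )
        if subtype_references and family in SUBTYPED_FAMILIES and family in subtype_references:
            query = rec.protein if rec.protein is not None else rec.cds
            call = assign_subtype(call, query, subtype_references[family])
        calls.append(call)
    return calls


def assign_subtype(
    call: OpsinCall,
    query: str,
    subtype_references: Mapping[str, str],
    margin: float = SUBTYPE_MARGIN,
) -> OpsinCall:
    """Nearest-subtype assignment with a margin rule: label only when the
    best normalised score beats the runner-up by at least ``margin``;
    otherwise the subtype stays unset (ambiguous)."""
    scored = []
    prot = _as_protein(query)
    for sid, sseq in subtype_references.items():
        ref = _as_protein(sseq)
        self_score = local_align_score(ref, ref)
        s = local_align_score(prot, ref) / self_score if self_score > 0 else 0.0
        scored.append((sid, s))
    scored.sort(key=lambda x: -x[1])
    call.subtype = None
    if len(scored) == 1 or scored[0][1] - scored[1][1] >= margin:
        call.subtype = scored[0][0]
    return call


def count_repertoire(
    calls: Iterable[OpsinCall],
    species: Sequence[str] | None = None,
    families: Sequence[str] = FAMILIES,
) -> pd.DataFrame:
    """species x family counts over *complete* calls only (pseudogenes and
    truncated genes are excluded from the repertoire)."""
    calls = list(calls)
    all_species = sorted(set(c.species for c in calls) | set(species or []))
    mat = pd.DataFrame(0, index=all_species, columns=list(families), dtype=int)
    for c in calls:
        if c.status == "complete" and c.family in mat.columns:
            mat.loc[c.species, c.family] += 1
    mat.index.name = "species"
    return mat


def calls_to_frame(calls: Iterable[OpsinCall]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": c.gene_id,
            "species": c.species,
            "family": c.family or "",
            "subtype": c.subtype or "",
            "status": c.status,
            "best_hit": c.best_hit_id or "",
            "score": c.score,
            "norm_score": round(c.normalized_score, 6),
            "n_count": c.n_count,
        }
        for c in calls
    ]
    return pd.DataFrame(rows)
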