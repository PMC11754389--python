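"""Readers, writers and the end-to-end pipeline.

Collections of strings are read from FASTA (multi-line records, headers
preserved) or from plain line-oriented text (one sequence per line,
identifiers are line numbers).  Distance matrices round-trip through TSV
with a header row of string ids followed by the square numeric block;
labels through two-column TSV.

:func:`pipeline_run` ties the three analysis phases together: sanitize
every string of a collection, compute the pairwise LIS-based k-gram
distance matrix, cluster with PAM, and score the sanitized clustering
against the clustering of the original collection (and against planted
truth labels when available).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .automaton import (
    MISSING,
    Alphabet,
    PatternSet,
    build_prefix_automaton,
    normalize_pattern_set,
)
from .cluster import ari, nmi, pam
from .distance import DistanceMatrix, distance_matrix
from .errors import DuplicateId, ParseError, ShapeMismatch
from .sanitize import SanitizeFailure, gfss, sfss, tfs
from .synth import SyntheticSpec, generate_cluster_collection, sample_forbidden_patterns


@dataclass
class StringCollection:
    """An ordered collection of identified sequences."""

    records: list[tuple[str, str]]
    source_format: str

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    @property
    def sequences(self) -> list[str]:
        return [seq for _, seq in self.records]

    def __len__(self) -> int:
        return len(self.records)


def read_strings(
    path, format: str = "auto", allow_missing: bool = False
) -> StringCollection:
    """Read a string collection from FASTA or line-oriented text.

    ``format='auto'`` sniffs FASTA by a leading ``'>'``.  Unless
    ``allow_missing`` is set, sequences containing the reserved ``'#'``
    marker are rejected (they are partial strings, not sanitizable input).
    """
    path = Path(path)
    text = path.read_text()
    if format == "auto":
        format = "fasta" if text.lstrip().startswith(">") else "lines"

    records: list[tuple[str, str]] = []
    if format == "fasta":
        for rec in SeqIO.parse(path, "fasta"):
            records.append((rec.id, str(rec.seq)))
        if not records and text.strip():
            raise ParseError(f"{path}: no FASTA records found")
    elif format == "lines":
        for lineno, line in enumerate(text.splitlines(), start=1):
            seq = line.strip()
            if not seq:
                raise ParseError(f"{path}:{lineno}: blank line in sequence file")
            records.append((str(lineno), seq))
    else:
        raise ParseError(f"unknown format {format!r}")

    seen: set[str] = set()
    for rid, seq in records:
        if rid in seen:
            raise DuplicateId(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
        if not allow_missing and MISSING in seq:
            raise ParseError(
                f"{path}: record {rid!r} contains the reserved symbol '#'"
            )
    return StringCollection(records=records, source_format=format)


def write_strings(collection: StringCollection, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or collection.source_format
    if fmt == "fasta":
        recs = [
            SeqRecord(Seq(seq), id=rid, description="")
            for rid, seq in collection.records
        ]
        SeqIO.write(recs, path, "fasta")
    else:
        path.write_text("".join(seq + "\n" for _, seq in collection.records))


def read_patterns(path, alphabet: Alphabet | None = None) -> list[str]:
    """Read a pattern file: one pattern per line, '>'-comments ignored."""
    raw: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if line.startswith(">"):
            continue
        p = line.strip()
        if not p:
            raise ParseError(f"{path}:{lineno}: blank pattern line")
        raw.append(p)
    return raw


def write_matrix(matrix: DistanceMatrix, ids, path) -> None:
    df = pd.DataFrame(matrix.values, index=list(ids), columns=list(ids))
    df.to_csv(path, sep="\t", index_label="id")


def read_matrix(path) -> tuple[DistanceMatrix, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    if values.shape[0] != values.shape[1]:
        raise ShapeMismatch(f"{path}: matrix is not square")
    if not np.array_equal(values, values.T):
        raise ShapeMismatch(f"{path}: matrix is not symmetric")
    return DistanceMatrix(values=values), [str(c) for c in df.columns]


def write_labels(ids, labels, path) -> None:
    pd.DataFrame({"id": list(ids), "label": list(labels)}).to_csv(
        path, sep="\t", index=False
    )


def read_labels(path) -> tuple[list[str], list[int]]:
    df = pd.read_csv(path, sep="\t")
    return [str(i) for i in df["id"]], [int(v) for v in df["label"]]


@dataclass
class PipelineConfig:
    """Configuration of one sanitize-then-cluster run.

    Exactly one of ``strings_path`` / ``synthetic`` provides the input
    collection; ``patterns_path`` may be omitted when ``synthetic`` also
    samples the antidictionary.
    """

    k: int
    K: int
    method: str = "sfss"  # sfss | gfss
    seed: int = 0
    strings_path: str | None = None
    patterns_path: str | None = None
    synthetic: SyntheticSpec | None = None
    truth_path: str | None = None
    outdir: str | None = None
    alphabet: Alphabet | None = None


def pipeline_run(config: PipelineConfig) -> dict:
    """Run sanitization, distance computation and clustering end to end.

    Returns a JSON-serializable report with the clustering-agreement scores
    between the original-data clustering and the sanitized-data clustering
    (and against truth labels when known).  Artifacts (sanitized strings,
    matrix, labels, report) are written under ``config.outdir`` if given.
    Records whose sanitization fails are retained with an empty sequence
    and listed in the report.
    """
    truth: list[int] | None = None
    if config.synthetic is not None:
        strings, truth = generate_cluster_collection(config.synthetic)
        ids = [f"s{i}" for i in range(len(strings))]
        alphabet = config.synthetic.alphabet
        rng = np.random.default_rng(config.synthetic.rng_seed + 1)
        patterns = sample_forbidden_patterns(
            "space",
            alphabet=alphabet,
            k=config.k,
            rng=rng,
            fraction=config.synthetic.fraction,
        )
    else:
        coll = read_strings(config.strings_path)
        ids, strings = coll.ids, coll.sequences
        alphabet = config.alphabet or Alphabet.from_strings(strings)
        raw = read_patterns(config.patterns_path)
        patterns = normalize_pattern_set(raw, alphabet)

    if config.truth_path is not None:
        _, truth = read_labels(config.truth_path)

    automaton = build_prefix_automaton(patterns, alphabet)
    sanitized: list[str] = []
    failures: list[dict] = []
    for rid, w in zip(ids, strings):
        if config.method == "sfss":
            y = sfss(w, config.k, patterns, alphabet=alphabet, automaton=automaton)
        elif config.method == "gfss":
            y = gfss(w, config.k, patterns)
        elif config.method == "tfs":
            y = tfs(w, config.k, patterns).text
        else:
            raise ValueError(f"unknown sanitization method {config.method!r}")
        if isinstance(y, SanitizeFailure):
            failures.append({"id": rid, "gap": y.gap_index, "reason": y.reason})
            y = ""
        sanitized.append(y)

    usable = [i for i, y in enumerate(sanitized) if len(y) >= config.k]
    original_matrix = distance_matrix([strings[i] for i in usable], config.k)
    sanitized_matrix = distance_matrix([sanitized[i] for i in usable], config.k)

    clustering_original = pam(original_matrix, config.K, seed=config.seed)
    clustering_sanitized = pam(sanitized_matrix, config.K, seed=config.seed)

    report = {
        "n_strings": len(strings),
        "n_used": len(usable),
        "method": config.method,
        "k": config.k,
        "K": config.K,
        "n_patterns": len(patterns),
        "failures": failures,
        "nmi_original_vs_sanitized": nmi(
            clustering_original.labels, clustering_sanitized.labels
        ),
        "ari_original_vs_sanitized": ari(
            clustering_original.labels, clustering_sanitized.labels
        ),
        "cost_original": clustering_original.cost,
        "cost_sanitized": clustering_sanitized.cost,
    }
    if truth is not None:
        truth_used = [truth[i] for i in usable]
        report["nmi_truth_vs_sanitized"] = nmi(truth_used, clustering_sanitized.labels)
        report["ari_truth_vs_sanitized"] = ari(truth_used, clustering_sanitized.labels)
        report["nmi_truth_vs_original"] = nmi(truth_used, clustering_original.labels)

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_strings(
            StringCollection(
                records=[(ids[i], sanitized[i]) for i in range(len(ids))],
                source_format="lines",
            ),
            outdir / "sanitized.txt",
        )
        used_ids = [ids[i] for i in usable]
        write_matrix(sanitized_matrix, used_ids, outdir / "matrix.tsv")
        write_labels(used_ids, clustering_sanitized.labels, outdir / "labels.tsv")
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report
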