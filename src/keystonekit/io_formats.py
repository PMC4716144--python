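"""Shared data containers and readers/writers for every external format.

The pipeline's substrates are plain text: expression matrices as TSV
(genes x samples) with a two-column sample->group map, gene-set collections
as GMT, gene-word corpora as JSON-lines (one document per gene), and
single-channel grayscale TIFF/PNG islet images.  Parsing is strict and
order-preserving; log transforms and any normalisation happen downstream so
that raw inputs stay auditable.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# --------------------------------------------------------------------------
# tokenisation (shared by corpus IO and phrase mining)

_TOKEN_RE = re.compile(r"[0-9a-z]+(?:-[0-9a-z]+)*")


def tokenize(text: str) -> list[str]:
    """Lowercase and split on non-alphanumeric boundaries, keeping internal
    hyphens so that forms like ``insulin-responsive`` survive as one token.

    No stemming and no stop-word removal: the word outputs this pipeline
    feeds (word clouds, phrase tables) rely on surface forms.
    """
    return _TOKEN_RE.findall(text.lower())


# --------------------------------------------------------------------------
# containers


@dataclass
class ExpressionMatrix:
    """Genes x samples raw (pre-log) intensity table with a sample->group map."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), float
    groups: dict[str, str]  # sample_id -> condition label

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise FormatError(f"duplicated gene id {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise FormatError(f"duplicated sample id {dup!r}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("non-finite intensity values")
        missing = [s for s in self.sample_ids if s not in self.groups]
        if missing:
            raise FormatError(f"samples missing from group map: {missing}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == group]

    def group_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.groups[s], None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GeneSetCollection:
    """Opaque user-supplied gene sets (pathways): set_id -> (description, members)."""

    sets: dict[str, tuple[str, list[str]]]

    def __post_init__(self) -> None:
        for sid, (_, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {sid!r} is empty")

    def members(self, set_id: str) -> list[str]:
        return self.sets[set_id][1]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


@dataclass
class Corpus:
    """One gene-word document per gene: gene_id -> token multiset."""

    documents: dict[str, Counter]

    def __post_init__(self) -> None:
        for gene, doc in self.documents.items():
            if not doc:
                raise FormatError(f"empty document for gene {gene!r}")
            for tok in doc:
                if re.search(r"\s", tok):
                    raise FormatError(f"token with whitespace in {gene!r}: {tok!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.documents)

    def vocabulary(self) -> list[str]:
        vocab: dict[str, None] = {}
        for doc in self.documents.values():
            for tok in doc:
                vocab.setdefault(tok, None)
        return sorted(vocab)

    def __len__(self) -> int:
        return len(self.documents)


@dataclass
class ChannelImage:
    """A single fluorescence channel as an integer intensity grid."""

    pixels: np.ndarray
    bit_depth: int
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.bit_depth not in (8, 16):
            raise FormatError(f"bit depth must be 8 or 16, got {self.bit_depth}")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise FormatError("pixels must be integer-typed")
        lo, hi = int(self.pixels.min(initial=0)), int(self.pixels.max(initial=0))
        if lo < 0 or hi > 2**self.bit_depth - 1:
            raise FormatError(
                f"intensities [{lo}, {hi}] outside [0, {2**self.bit_depth - 1}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    raise ValueError("no duplicate present")


# --------------------------------------------------------------------------
# expression TSV


def read_expression_tsv(path: str | Path, group_map_path: str | Path) -> ExpressionMatrix:
    """Read a genes-x-samples TSV (first column gene ids, header sample ids)
    plus a two-column (sample_id, group) TSV map."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != len(sample_ids) + 1:
            raise FormatError(f"{path}:{lineno}: expected {len(sample_ids) + 1} fields")
        gene_ids.append(fields[0])
        row = []
        for col, cell in enumerate(fields[1:], start=2):
            try:
                row.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric cell {cell!r} in column {col}"
                ) from None
        rows.append(row)
    groups = read_group_map(group_map_path)
    return ExpressionMatrix(gene_ids, sample_ids, np.array(rows, dtype=float), groups)


def read_group_map(path: str | Path) -> dict[str, str]:
    path = Path(path)
    groups: dict[str, str] = {}
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        fields = ln.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 fields (sample, group)")
        sample, group = fields
        if sample in groups:
            raise FormatError(f"{path}:{lineno}: duplicated sample {sample!r}")
        groups[sample] = group
    return groups


def write_expression_tsv(
    matrix: ExpressionMatrix, path: str | Path, group_map_path: str | Path
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene\t" + "\t".join(matrix.sample_ids) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    with Path(group_map_path).open("w") as fh:
        for s in matrix.sample_ids:
            fh.write(f"{s}\t{matrix.groups[s]}\n")


# --------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Standard GMT dialect: set_id TAB description TAB member1 TAB member2 ...

    Members are deduplicated preserving first occurrence.
    """
    path = Path(path)
    sets: dict[str, tuple[str, list[str]]] = {}
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        fields = ln.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs >=3 fields")
        sid, desc = fields[0], fields[1]
        if sid in sets:
            raise FormatError(f"{path}:{lineno}: duplicated set id {sid!r}")
        members = list(dict.fromkeys(m for m in fields[2:] if m))
        sets[sid] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for sid, (desc, members) in collection.sets.items():
            fh.write("\t".join([sid, desc, *members]) + "\n")


# --------------------------------------------------------------------------
# corpus JSONL


def read_corpus_jsonl(path: str | Path) -> Corpus:
    """One JSON object per line with a ``gene`` field and either ``text``
    (tokenised here) or ``tokens`` (taken verbatim, lowercased)."""
    path = Path(path)
    docs: dict[str, Counter] = {}
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        try:
            obj = json.loads(ln)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}:{lineno}: malformed JSON ({exc.msg})") from None
        if "gene" not in obj:
            raise FormatError(f"{path}:{lineno}: missing 'gene' field")
        gene = obj["gene"]
        if gene in docs:
            raise FormatError(f"{path}:{lineno}: duplicate gene {gene!r}")
        if "tokens" in obj:
            tokens = [str(t).lower() for t in obj["tokens"]]
        elif "text" in obj:
            tokens = tokenize(obj["text"])
        else:
            raise FormatError(f"{path}:{lineno}: need 'text' or 'tokens'")
        if not tokens:
            raise FormatError(f"{path}:{lineno}: empty document for {gene!r}")
        docs[gene] = Counter(tokens)
    return Corpus(docs)


def write_corpus_jsonl(corpus: Corpus, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for gene, doc in corpus.documents.items():
            tokens = [t for t, c in doc.items() for _ in range(c)]
            fh.write(json.dumps({"gene": gene, "tokens": tokens}) + "\n")


# --------------------------------------------------------------------------
# images


def load_channel_image(path: str | Path, channel_label: str = "") -> ChannelImage:
    """Load a single-channel grayscale TIFF or PNG (8- or 16-bit)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        arr = iio.imread(str(path))
    if arr.ndim == 3:
        raise FormatError(
            f"{path}: multi-channel (RGB) input; extract one channel per file"
        )
    if np.issubdtype(arr.dtype, np.floating):
        raise FormatError(f"{path}: float pixel data; expected 8- or 16-bit integers")
    bit_depth = 16 if arr.dtype.itemsize >= 2 else 8
    return ChannelImage(arr.astype(np.int64), bit_depth, channel_label)


def save_channel_image(image: ChannelImage, path: str | Path) -> None:
    path = Path(path)
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    arr = image.pixels.astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(path), arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(str(path), arr)


# --------------------------------------------------------------------------
# result tables


def write_result_tsv(
    frame: pd.DataFrame,
    path: str | Path,
    params: Mapping[str, object] | None = None,
) -> None:
    """Write a results table as TSV with a leading ``#`` comment block that
    records the parameters (and seed) used to produce it."""
    path = Path(path)
    with path.open("w") as fh:
        for key, val in (params or {}).items():
            fh.write(f"# {key}: {val}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_result_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
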