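"""Case-control genotype tables: data model, CSV I/O and stratified splitting.

A dataset is a subjects x loci matrix of ternary genotypes. Each locus has an
ordered triple of state labels (homozygous-major, heterozygous,
homozygous-minor, e.g. ``"A", "AG", "G"``); genotypes are stored as small
integers 0/1/2 indexing that order, with ``-1`` marking a missing call.
The phenotype is binary: case (affected) = 1, control = 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

MISSING = -1

#: genotype strings treated as missing calls by default
DEFAULT_MISSING_TOKENS = ("", "NA")


@dataclass(frozen=True)
class Locus:
    """A biallelic SNP locus with three ordered genotype states.

    State order is fixed at construction and used everywhere states are
    indexed: CPT columns, one-hot columns, tie-breaking.
    """

    locus_id: str
    state_labels: tuple[str, str, str]
    gene_label: str | None = None

    def __post_init__(self) -> None:
        if len(self.state_labels) != 3:
            raise ValueError(
                f"locus {self.locus_id!r}: expected 3 state labels, "
                f"got {len(self.state_labels)}"
            )
        if len(set(self.state_labels)) != 3:
            raise ValueError(f"locus {self.locus_id!r}: state labels must be distinct")
        object.__setattr__(self, "state_labels", tuple(self.state_labels))

    def state_index(self, label: str) -> int:
        try:
            return self.state_labels.index(label)
        except ValueError:
            raise KeyError(
                f"locus {self.locus_id!r}: unknown genotype {label!r} "
                f"(declared states {self.state_labels})"
            ) from None

    def heterozygote_index(self) -> int:
        """Index of the heterozygous state, inferred from label structure.

        Single-letter labels ("A") and doubled letters ("AA") are homozygotes;
        a two-character label with distinct characters ("AG") is the
        heterozygote.
        """
        hets = [
            i
            for i, lab in enumerate(self.state_labels)
            if len(lab) == 2 and lab[0] != lab[1]
        ]
        if len(hets) != 1:
            raise ValueError(
                f"locus {self.locus_id!r}: cannot identify a unique heterozygote "
                f"among {self.state_labels}"
            )
        return hets[0]


@dataclass
class GenotypeDataset:
    """Subjects x loci genotype matrix with a binary case/control phenotype."""

    subjects: list[str]
    loci: list[Locus]
    genotypes: np.ndarray  # (n_subjects, n_loci) int8, MISSING = -1
    phenotype: np.ndarray  # (n_subjects,) int8 in {0, 1}

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        n, m = self.genotypes.shape
        if len(self.subjects) != n:
            raise ValueError("subject list and genotype matrix disagree on n")
        if len(self.loci) != m:
            raise ValueError("locus list and genotype matrix disagree on m")
        if len(set(self.subjects)) != n:
            seen: set[str] = set()
            dup = next(s for s in self.subjects if s in seen or seen.add(s))
            raise ValueError(f"duplicate subject ID {dup!r}")
        bad = (self.genotypes < MISSING) | (self.genotypes > 2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {self.genotypes[i, j]} at subject "
                f"{self.subjects[i]!r}, locus {self.loci[j].locus_id!r}"
            )
        if not np.isin(self.phenotype, (0, 1)).all():
            raise ValueError("phenotype must be binary 0/1")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, locus_id: str) -> int:
        for j, loc in enumerate(self.loci):
            if loc.locus_id == locus_id:
                return j
        raise KeyError(f"locus {locus_id!r} not in dataset")

    def subset(self, rows: np.ndarray) -> "GenotypeDataset":
        rows = np.asarray(rows)
        return GenotypeDataset(
            subjects=[self.subjects[i] for i in rows],
            loci=list(self.loci),
            genotypes=self.genotypes[rows].copy(),
            phenotype=self.phenotype[rows].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Decode to a labelled DataFrame (missing as empty string)."""
        cols: dict[str, object] = {"subject_id": self.subjects}
        cols["phenotype"] = self.phenotype.astype(int)
        for j, loc in enumerate(self.loci):
            col = self.genotypes[:, j]
            cols[loc.locus_id] = [
                "" if g == MISSING else loc.state_labels[g] for g in col
            ]
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class SplitPlan:
    """Train/test partition plan; the study design splits 7:3."""

    train_fraction: float = 0.7
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class TableSchema:
    """Column mapping for a genotype CSV: loci, state labels, codings."""

    loci: tuple[Locus, ...]
    subject_column: str = "subject_id"
    phenotype_column: str = "phenotype"
    # strings mapping to case (1) / control (0); numerals handled natively
    case_tokens: tuple[str, ...] = ("1", "case", "yes")
    control_tokens: tuple[str, ...] = ("0", "control", "no")
    missing_tokens: tuple[str, ...] = DEFAULT_MISSING_TOKENS

    @classmethod
    def from_file(cls, path: str | Path) -> "TableSchema":
        """Load a schema from YAML or JSON.

        Expected shape::

            loci:
              - {locus_id: rs1042522, states: [C, CG, G], gene: TP53}
            subject_column: subject_id      # optional
            phenotype_column: phenotype     # optional
            missing_tokens: ["", "NA"]      # optional
        """
        path = Path(path)
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        loci = tuple(
            Locus(d["locus_id"], tuple(d["states"]), d.get("gene"))
            for d in raw["loci"]
        )
        kw = {}
        for key in ("subject_column", "phenotype_column"):
            if key in raw:
                kw[key] = raw[key]
        for key in ("case_tokens", "control_tokens", "missing_tokens"):
            if key in raw:
                kw[key] = tuple(raw[key])
        return cls(loci=loci, **kw)


def read_genotype_table(path: str | Path, schema: TableSchema) -> GenotypeDataset:
    """Read a genotype CSV (one row per subject) into a :class:`GenotypeDataset`.

    Genotype strings must match the locus's declared state labels or a missing
    token; states are encoded 0/1/2 in declared order and row order is
    preserved.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in (schema.subject_column, schema.phenotype_column):
        if col not in df.columns:
            raise ValueError(f"required column {col!r} missing from {path}")
    subjects = df[schema.subject_column].tolist()
    if len(set(subjects)) != len(subjects):
        seen: set[str] = set()
        dup = next(s for s in subjects if s in seen or seen.add(s))
        raise ValueError(f"duplicate subject ID {dup!r} in {path}")

    phen = np.empty(len(df), dtype=np.int8)
    case = {t.lower() for t in schema.case_tokens}
    control = {t.lower() for t in schema.control_tokens}
    for i, v in enumerate(df[schema.phenotype_column]):
        v = v.strip().lower()
        if v in case:
            phen[i] = 1
        elif v in control:
            phen[i] = 0
        else:
            raise ValueError(f"row {i}: unrecognised phenotype value {v!r}")

    geno = np.full((len(df), len(schema.loci)), MISSING, dtype=np.int8)
    missing = set(schema.missing_tokens)
    for j, loc in enumerate(schema.loci):
        if loc.locus_id not in df.columns:
            raise ValueError(f"locus column {loc.locus_id!r} missing from {path}")
        lut = {lab: k for k, lab in enumerate(loc.state_labels)}
        for i, v in enumerate(df[loc.locus_id]):
            v = v.strip()
            if v in missing:
                continue
            if v not in lut:
                raise ValueError(
                    f"unknown genotype {v!r} at row {i} "
                    f"(subject {subjects[i]!r}), locus {loc.locus_id!r}; "
                    f"declared states {loc.state_labels}"
                )
            geno[i, j] = lut[v]
    return GenotypeDataset(subjects, list(schema.loci), geno, phen)


def write_genotype_table(ds: GenotypeDataset, path: str | Path) -> None:
    """Write the dataset back out in the same CSV dialect the reader accepts."""
    ds.to_frame().to_csv(path, index=False)


def stratified_split(
    ds: GenotypeDataset, plan: SplitPlan
) -> tuple[GenotypeDataset, GenotypeDataset]:
    """Split into train/test, by default stratified on phenotype.

    Per-class train size is ``floor(fraction * class_size + 0.5)``; the
    remainder goes to test. The same seed always yields the same partition.
    """
    classes = np.unique(ds.phenotype)
    if len(classes) < 2:
        raise ValueError("both phenotype classes must be present before splitting")
    rng = np.random.default_rng(plan.seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    if plan.stratified:
        groups = [np.flatnonzero(ds.phenotype == c) for c in classes]
    else:
        groups = [np.arange(ds.n_subjects)]
    for idx in groups:
        if len(idx) < 2:
            raise ValueError("each phenotype class needs at least 2 members")
        perm = rng.permutation(idx)
        n_train = int(np.floor(plan.train_fraction * len(idx) + 0.5))
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    train = np.sort(np.concatenate(train_idx))
    test = np.sort(np.concatenate(test_idx))
    return ds.subset(train), ds.subset(test)


def write_split_manifest(
    train: GenotypeDataset, test: GenotypeDataset, path: str | Path
) -> None:
    rows = [(s, "train") for s in train.subjects] + [
        (s, "test") for s in test.subjects
    ]
    pd.DataFrame(rows, columns=["subject_id", "partition"]).to_csv(path, index=False)


def complete_cases(
    ds: GenotypeDataset, loci: Sequence[str] | None = None
) -> GenotypeDataset:
    """Subjects with no missing genotype at any of the listed loci.

    ``loci`` defaults to all loci. The input dataset is left unmodified.
    """
    if loci is None:
        loci = [loc.locus_id for loc in ds.loci]
    cols = [ds.locus_index(l) for l in loci]
    keep = np.flatnonzero((ds.genotypes[:, cols] != MISSING).all(axis=1))
    if len(keep) == 0:
        raise ValueError(
            "no subject is complete at all listed loci; relax the locus list"
        )
    return ds.subset(keep)
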