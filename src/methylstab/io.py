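"""Readers and writers for the tabular formats the pipeline touches.

Beta-value and detection p-value matrices are TSV files with a probe-ID
first column and sample IDs in the header; sample sheets are CSV with one
row per array; probe annotation comes from an Illumina-manifest-style CSV.
Missing beta values use the token ``NA`` and are excluded pairwise from
all downstream metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    EmptyDesignError,
    FormatError,
    RangeError,
    SchemaError,
)

logger = logging.getLogger(__name__)

#: Closed vocabulary of RefGene location groups (first manifest entry wins).
REFGENE_GROUPS = ("TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR", "none")

#: Fixed column order of the serialized per-probe stability table.
STABILITY_COLUMNS_PREFIX = ("probe_id",)


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation beta fractions in [0, 1].

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by probe ID, columns by sample ID, cells in [0, 1]
        or NaN for missing.
    detection_p : pandas.DataFrame, optional
        Per-cell detection p-values with identical index and columns.
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def validate(self) -> None:
        idx, cols = self.values.index, self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate probe ID {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample ID {dup!r}")
        vals = self.values.to_numpy(dtype=float)
        bad = (vals < 0.0) | (vals > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise RangeError(
                f"beta value {vals[i, j]!r} outside [0, 1] at probe "
                f"{idx[i]!r}, sample {cols[j]!r}"
            )
        if self.detection_p is not None:
            dp = self.detection_p
            if not (dp.index.equals(idx) and dp.columns.equals(cols)):
                raise AlignmentError(
                    "detection p-value matrix does not share the beta "
                    "matrix's probe/sample ordering "
                    f"(beta {self.values.shape}, detection {dp.shape})"
                )

    def subset(
        self, probes: pd.Index | None = None, samples: pd.Index | None = None
    ) -> "BetaMatrix":
        """Return a new matrix restricted to the given probes/samples."""
        values = self.values
        detp = self.detection_p
        if probes is not None:
            values = values.loc[probes]
            detp = detp.loc[probes] if detp is not None else None
        if samples is not None:
            values = values[samples]
            detp = detp[samples] if detp is not None else None
        return BetaMatrix(values, detp)


@dataclass
class StudyDesign:
    """Pairing of subjects to one sample per timepoint within a cohort.

    ``pairs`` holds one (subject_id, sample_T1, sample_T2) triple per
    subject; when a (subject, timepoint) has technical replicates the
    first sample appears in the pair and the full list is kept in
    ``replicates`` keyed by (subject_id, timepoint).
    """

    cohort_id: str
    pairs: list[tuple[str, str, str]]
    replicates: dict[tuple[str, int], list[str]] = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.pairs)

    def samples_for(self, subject_id: str, timepoint: int) -> list[str]:
        """All sample IDs measuring one subject at one timepoint."""
        key = (subject_id, timepoint)
        if key in self.replicates:
            return list(self.replicates[key])
        for subj, s1, s2 in self.pairs:
            if subj == subject_id:
                return [s1 if timepoint == 1 else s2]
        raise KeyError(subject_id)

    def all_sample_ids(self) -> list[str]:
        """Every sample referenced by the design, replicates included."""
        out: list[str] = []
        for subj, s1, s2 in self.pairs:
            for tp, primary in ((1, s1), (2, s2)):
                out.extend(self.replicates.get((subj, tp), [primary]))
        return out

    def drop_samples(self, bad: set[str]) -> "StudyDesign":
        """Remove samples; a subject losing all samples at either
        timepoint loses its pair."""
        pairs: list[tuple[str, str, str]] = []
        replicates: dict[tuple[str, int], list[str]] = {}
        for subj, s1, s2 in self.pairs:
            kept: dict[int, list[str]] = {}
            for tp, primary in ((1, s1), (2, s2)):
                ids = self.replicates.get((subj, tp), [primary])
                kept[tp] = [s for s in ids if s not in bad]
            if kept[1] and kept[2]:
                pairs.append((subj, kept[1][0], kept[2][0]))
                for tp in (1, 2):
                    if len(kept[tp]) > 1:
                        replicates[(subj, tp)] = kept[tp]
            else:
                logger.warning(
                    "cohort %s: subject %s dropped (sample removed by filter)",
                    self.cohort_id,
                    subj,
                )
        return StudyDesign(self.cohort_id, pairs, replicates)


@dataclass
class ProbeAnnotation:
    """Manifest-derived per-probe metadata.

    ``table`` is indexed by probe ID with columns chromosome, coordinate,
    gene, refgene_group, design_type, snp_flag.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise FormatError(f"duplicate probe ID {dup!r} in annotation")
        bad = set(self.table["refgene_group"]) - set(REFGENE_GROUPS)
        if bad:
            raise FormatError(f"refgene_group outside vocabulary: {sorted(bad)}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    @property
    def snp_flag(self) -> pd.Series:
        return self.table["snp_flag"]


def read_beta_matrix(path, detp_path=None) -> BetaMatrix:
    """Read a beta-value TSV (probe rows, sample columns), optionally with
    an aligned detection p-value TSV of the same shape.

    Raises :class:`FormatError` on duplicate IDs, :class:`RangeError` on
    values outside [0, 1], :class:`AlignmentError` on shape mismatch.
    """
    values = _read_matrix_tsv(path)
    detp = _read_matrix_tsv(detp_path) if detp_path is not None else None
    if detp is not None and not (
        detp.index.equals(values.index) and detp.columns.equals(values.columns)
    ):
        raise AlignmentError(
            f"detection matrix {detp_path} does not align with beta matrix {path}"
        )
    return BetaMatrix(values, detp)


def _read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        return df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric cell in {path}: {exc}") from exc


def write_beta_matrix(beta: BetaMatrix, path, detp_path=None) -> None:
    """Write a beta matrix (and optionally its detection matrix) as TSV."""
    beta.values.to_csv(path, sep="\t", na_rep="NA", index_label="probe_id",
                       float_format="%.10g")
    if detp_path is not None:
        if beta.detection_p is None:
            raise AlignmentError("no detection p-values to write")
        beta.detection_p.to_csv(detp_path, sep="\t", na_rep="NA",
                                index_label="probe_id", float_format="%.10g")


def read_sample_sheet(path, cohort_id: str | None = None):
    """Assemble study designs from a sample sheet CSV.

    The sheet has columns cohort_id, subject_id, sample_id, timepoint
    (1 or 2). Subjects missing either timepoint are dropped with a logged
    warning; extra samples for one (subject, timepoint) are recorded as
    replicates.

    Returns a list of :class:`StudyDesign`, one per cohort in file order,
    or a single design when ``cohort_id`` is given.
    """
    sheet = pd.read_csv(path, dtype=str)
    required = {"cohort_id", "subject_id", "sample_id", "timepoint"}
    missing = required - set(sheet.columns)
    if missing:
        raise SchemaError(f"sample sheet missing column(s) {sorted(missing)}")
    bad_tp = ~sheet["timepoint"].isin(["1", "2"])
    if bad_tp.any():
        tok = sheet.loc[bad_tp, "timepoint"].iloc[0]
        raise FormatError(f"unknown timepoint token {tok!r} (expected 1 or 2)")
    sheet["timepoint"] = sheet["timepoint"].astype(int)

    designs: list[StudyDesign] = []
    for cid in sheet["cohort_id"].unique():
        sub = sheet[sheet["cohort_id"] == cid]
        pairs: list[tuple[str, str, str]] = []
        replicates: dict[tuple[str, int], list[str]] = {}
        for subj in sub["subject_id"].unique():
            rows = sub[sub["subject_id"] == subj]
            by_tp = {
                tp: list(rows.loc[rows["timepoint"] == tp, "sample_id"])
                for tp in (1, 2)
            }
            if not by_tp[1] or not by_tp[2]:
                logger.warning(
                    "cohort %s: subject %s lacks timepoint %d and was dropped",
                    cid, subj, 1 if not by_tp[1] else 2,
                )
                continue
            pairs.append((subj, by_tp[1][0], by_tp[2][0]))
            for tp in (1, 2):
                if len(by_tp[tp]) > 1:
                    replicates[(subj, tp)] = by_tp[tp]
        design = StudyDesign(str(cid), pairs, replicates)
        if design.n_subjects == 0:
            raise EmptyDesignError(f"cohort {cid}: no complete subject pairs")
        designs.append(design)
    if not designs:
        raise EmptyDesignError("sample sheet contains no cohorts")
    if cohort_id is not None:
        for d in designs:
            if d.cohort_id == str(cohort_id):
                return d
        raise EmptyDesignError(f"cohort {cohort_id} not present in sheet")
    return designs


_MANIFEST_COLUMNS = (
    "IlmnID", "CHR", "MAPINFO", "UCSC_RefGene_Name",
    "UCSC_RefGene_Group", "Infinium_Design_Type",
)


def read_manifest(path, snp_column: str = "Probe_SNPs") -> ProbeAnnotation:
    """Read an Illumina-manifest-style CSV into a :class:`ProbeAnnotation`.

    Multi-entry RefGene fields (semicolon-separated) collapse to the first
    entry; an empty group maps to ``"none"``. Any non-empty value in
    ``snp_column`` sets the probe's SNP flag — the manifest's SNP distance
    and allele details are not modelled.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in (*_MANIFEST_COLUMNS, snp_column) if c not in df.columns]
    if missing:
        raise SchemaError(f"manifest missing column(s) {missing}")

    def first_entry(value: str) -> str:
        return value.split(";")[0].strip() if value else ""

    group = df["UCSC_RefGene_Group"].map(first_entry)
    group = group.where(group.isin(REFGENE_GROUPS[:-1]), "none")
    table = pd.DataFrame(
        {
            "chromosome": df["CHR"].str.strip().to_numpy(),
            "coordinate": pd.to_numeric(df["MAPINFO"], errors="coerce")
            .astype("Int64")
            .to_numpy(),
            "gene": df["UCSC_RefGene_Name"].map(first_entry).to_numpy(),
            "refgene_group": group.to_numpy(),
            "design_type": df["Infinium_Design_Type"].str.strip().to_numpy(),
            "snp_flag": (df[snp_column].str.strip() != "").to_numpy(),
        },
        index=pd.Index(df["IlmnID"].astype(str), name="probe_id"),
    )
    return ProbeAnnotation(table)


def write_stability_table(table: pd.DataFrame, path) -> None:
    """Serialize the per-probe stability/category table as TSV.

    Rows are sorted by probe ID, so the output is identical for any input
    probe order; floats keep >= 6 significant digits and booleans become
    0/1.
    """
    out = table.sort_index()
    out = out.copy()
    for col in out.columns:
        if out[col].dtype == bool:
            out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", na_rep="NA", index_label="probe_id",
               float_format="%.6g")


def read_stability_table(path) -> pd.DataFrame:
    """Read back a stability table written by :func:`write_stability_table`."""
    return pd.read_csv(path, sep="\t", index_col="probe_id",
                       na_values=["NA"], keep_default_na=False)
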