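"""Input/output for label-free AP-MS quantification data.

Reads peptide-level quantification tables (a Progenesis-export-like dialect),
sample sheets, FASTA sequence lengths, contaminant accession lists, protein
feature annotations and prior-interaction edge lists; aggregates peptides to
the protein level; and writes all pipeline outputs.

The quantification table dialect is: columns ``protein``, ``peptide`` followed
by paired per-sample columns ``<sample_id>.intensity`` and ``<sample_id>.sc``
(spectral count). Delimiter (tab or comma) is auto-detected and gzip input is
transparent. A cell with spectral count 0 is treated as undetected and its
intensity is stored as an explicit missing value, never as 0, so downstream
statistics can choose their own handling.
"""

from __future__ import annotations

import gzip
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO


class QuantIOError(Exception):
    """Base class for quantification-input errors."""


class DialectError(QuantIOError):
    """Input table columns do not match the declared dialect."""


class AggregationConflictError(QuantIOError):
    """Duplicate (protein, peptide, sample) measurements in the input."""


class ValidationError(QuantIOError):
    """A value violates an input invariant (e.g. negative intensity)."""


@dataclass(frozen=True)
class SampleMeta:
    """One LC-MS/MS run: which bait it purifies and which replicate it is."""

    sample_id: str
    bait_id: str
    replicate_index: int
    is_control_only: bool = False

    def __post_init__(self) -> None:
        if self.replicate_index < 1:
            raise ValidationError(
                f"replicate_index must be >= 1 for sample {self.sample_id!r}"
            )


@dataclass
class QuantMatrix:
    """Protein-level quantification for a multi-bait AP-MS experiment.

    Attributes
    ----------
    intensity : DataFrame, proteins x samples
        Summed peptide intensities; undetected cells are NaN.
    spectral_count : DataFrame, proteins x samples
        Summed spectral counts (int); 0 exactly where intensity is NaN.
    unique_peptides : DataFrame, proteins x baits
        Number of distinct peptide sequences of each protein detected in any
        sample of each bait.
    samples : list of SampleMeta, aligned with the intensity columns.
    """

    intensity: pd.DataFrame
    spectral_count: pd.DataFrame
    unique_peptides: pd.DataFrame
    samples: list[SampleMeta]

    @property
    def proteins(self) -> list[str]:
        return list(self.intensity.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensity.columns)

    @property
    def baits(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.bait_id, None)
        return list(seen)

    def samples_of_bait(self, bait_id: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.bait_id == bait_id]

    def validate(self) -> None:
        if list(self.intensity.index) != list(self.spectral_count.index):
            raise ValidationError("intensity/spectral_count protein index mismatch")
        if list(self.intensity.columns) != list(self.spectral_count.columns):
            raise ValidationError("intensity/spectral_count sample columns mismatch")
        if [s.sample_id for s in self.samples] != list(self.intensity.columns):
            raise ValidationError("sample metadata does not match matrix columns")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample_id in sample metadata")
        missing = self.intensity.isna().to_numpy()
        sc = self.spectral_count.to_numpy()
        if (sc[missing] != 0).any():
            raise ValidationError("missing intensity cell with nonzero spectral count")
        if np.nanmin(self.intensity.to_numpy(), initial=0.0) < 0:
            raise ValidationError("negative intensity")


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read a TSV sample sheet with columns sample_id, bait_id, replicate."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "bait_id", "replicate"}
    if not required.issubset(df.columns):
        raise DialectError(
            f"sample sheet must have columns {sorted(required)}, got {list(df.columns)}"
        )
    metas = [
        SampleMeta(row.sample_id, row.bait_id, int(row.replicate))
        for row in df.itertuples()
    ]
    ids = [m.sample_id for m in metas]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample_id in sample sheet")
    return metas


def _open_text(path: str | Path):
    p = Path(path)
    if p.suffix == ".gz":
        return gzip.open(p, "rt")
    return open(p)


def _detect_sep(path: str | Path) -> str:
    with _open_text(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_peptide_table(path: str | Path) -> pd.DataFrame:
    """Read the raw peptide-level table without aggregation."""
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep)
    if "protein" not in df.columns or "peptide" not in df.columns:
        raise DialectError("quant table must start with 'protein' and 'peptide' columns")
    return df


def read_quant_table(path: str | Path, sample_sheet: str | Path) -> QuantMatrix:
    """Read a peptide-level quant table and aggregate to a protein QuantMatrix.

    Peptide rows are rolled up to protein level by summing intensities and
    spectral counts per (protein, sample). ``unique_peptides[p, b]`` counts the
    distinct peptide sequences of protein ``p`` detected (spectral count > 0)
    in any sample of bait ``b``.
    """
    samples = read_sample_sheet(sample_sheet)
    df = read_peptide_table(path)
    return build_quant_matrix(df, samples)


def build_quant_matrix(df: pd.DataFrame, samples: list[SampleMeta]) -> QuantMatrix:
    """Aggregate an in-memory peptide table (dialect columns) to a QuantMatrix."""
    sample_ids = [s.sample_id for s in samples]
    declared = set(sample_ids)
    value_cols = [c for c in df.columns if c not in ("protein", "peptide")]
    for col in value_cols:
        m = re.fullmatch(r"(.+)\.(intensity|sc)", col)
        if m is None:
            raise DialectError(f"column {col!r} does not match '<sample>.intensity|sc'")
        if m.group(1) not in declared:
            raise DialectError(f"sample column {col!r} not declared in sample sheet")
    for sid in sample_ids:
        for suffix in (".intensity", ".sc"):
            if sid + suffix not in df.columns:
                raise DialectError(f"missing column {sid + suffix!r}")

    if df.duplicated(subset=["protein", "peptide"]).any():
        dupes = df.loc[df.duplicated(subset=["protein", "peptide"]), "peptide"]
        raise AggregationConflictError(
            f"duplicate (protein, peptide) rows, e.g. peptide {dupes.iloc[0]!r}"
        )
    if not df["peptide"].map(lambda s: isinstance(s, str) and len(s) > 0).all():
        raise ValidationError("empty peptide sequence")

    inten_cols = [f"{sid}.intensity" for sid in sample_ids]
    sc_cols = [f"{sid}.sc" for sid in sample_ids]
    inten = df[inten_cols].fillna(0.0).to_numpy(dtype=float)
    sc = df[sc_cols].fillna(0).to_numpy(dtype=int)
    if (inten < 0).any():
        raise ValidationError("negative intensity in quant table")
    if (sc < 0).any():
        raise ValidationError("negative spectral count in quant table")
    # sc == 0 marks an undetected peptide cell; its intensity is ignored
    inten = np.where(sc > 0, inten, 0.0)

    proteins = pd.Index(df["protein"]).unique()
    grp = df.groupby("protein", sort=False).indices
    n_p, n_s = len(proteins), len(sample_ids)
    agg_i = np.zeros((n_p, n_s))
    agg_sc = np.zeros((n_p, n_s), dtype=int)
    for i, prot in enumerate(proteins):
        rows = grp[prot]
        agg_i[i] = inten[rows].sum(axis=0)
        agg_sc[i] = sc[rows].sum(axis=0)

    intensity = pd.DataFrame(agg_i, index=proteins, columns=sample_ids)
    spectral_count = pd.DataFrame(agg_sc, index=proteins, columns=sample_ids)
    intensity = intensity.mask(spectral_count == 0)

    baits: list[str] = []
    for s in samples:
        if s.bait_id not in baits:
            baits.append(s.bait_id)
    up = pd.DataFrame(0, index=proteins, columns=baits, dtype=int)
    detected = sc > 0
    col_of = {sid: j for j, sid in enumerate(sample_ids)}
    for b in baits:
        cols = [col_of[sid] for s in samples if s.bait_id == b for sid in [s.sample_id]]
        any_det = detected[:, cols].any(axis=1)
        counts = (
            df.loc[any_det, ["protein", "peptide"]]
            .groupby("protein", sort=False)["peptide"]
            .nunique()
        )
        up.loc[counts.index, b] = counts
    qm = QuantMatrix(intensity, spectral_count, up, list(samples))
    qm.validate()
    return qm


_SP_HEADER = re.compile(r"^(?:sp|tr)\|([^|]+)\|")


def read_fasta_lengths(path: str | Path) -> dict[str, int]:
    """Map accession -> sequence length (residues) from a protein FASTA.

    The accession is the first whitespace-delimited header token, with the
    UniProt ``sp|ACC|NAME`` dialect unwrapped to ``ACC``. Duplicate accessions
    are allowed only if their lengths agree.
    """
    lengths: dict[str, int] = {}
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        token = rec.id
        if not token:
            raise ValidationError(f"unparsable FASTA header at record {i + 1}")
        m = _SP_HEADER.match(token)
        acc = m.group(1) if m else token
        L = len(rec.seq)
        if L == 0:
            raise ValidationError(f"empty sequence for {acc}")
        if acc in lengths and lengths[acc] != L:
            raise ValidationError(
                f"duplicate accession {acc} with conflicting lengths "
                f"{lengths[acc]} and {L}"
            )
        lengths[acc] = L
    return lengths


def read_contaminant_list(path: str | Path) -> set[str]:
    """Read one accession per line; '#' comments allowed; case preserved."""
    accs: set[str] = set()
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                accs.add(line)
    if not accs:
        import warnings

        warnings.warn(f"contaminant list {path} is empty", stacklevel=2)
    return accs


def read_prior_edges(path: str | Path) -> set[frozenset[str]]:
    """Read an undirected prior-interaction edge list (TSV protein_a, protein_b)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"protein_a", "protein_b"}.issubset(df.columns):
        raise DialectError("prior edge list needs columns protein_a, protein_b")
    return {frozenset((a, b)) for a, b in zip(df["protein_a"], df["protein_b"])}


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a protein feature table (TMD / signal peptide / N-glyc / disulphide).

    Returns a DataFrame indexed by accession with boolean feature columns and
    integer ``length_aa``.
    """
    df = pd.read_csv(path, sep="\t")
    required = {
        "protein_acc",
        "length_aa",
        "has_tmd",
        "has_signal_peptide",
        "has_nglyc",
        "has_disulphide",
    }
    if not required.issubset(df.columns):
        raise DialectError(f"annotation table needs columns {sorted(required)}")
    df = df.set_index("protein_acc")
    if (df["length_aa"] < 1).any():
        raise ValidationError("length_aa must be >= 1")
    for c in ("has_tmd", "has_signal_peptide", "has_nglyc", "has_disulphide"):
        df[c] = df[c].astype(bool)
    return df


# ---------------------------------------------------------------------------
# Output writing

HCIP_COLUMNS = [
    "bait_id",
    "protein_acc",
    "provenance",
    "p_value",
    "q_value",
    "log2fc",
    "unique_peptides",
    "sinq_score",
    "passed_filters",
]


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        if np.isnan(x):
            return "NA"
        return f"{x:.8g}"
    return str(x)


def write_outputs(records, summaries: dict, out_dir: str | Path) -> list[Path]:
    """Write hcips.tsv, edges.tsv and summary.json for a set of HCIP records.

    Rows are ordered deterministically (bait, then prey, lexicographic);
    numeric fields carry at least 6 significant digits.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    recs = sorted(records, key=lambda r: (r.bait_id, r.protein_acc))

    hcips_path = out / "hcips.tsv"
    with open(hcips_path, "w") as fh:
        fh.write("\t".join(HCIP_COLUMNS) + "\n")
        for r in recs:
            fh.write(
                "\t".join(
                    _fmt(getattr(r, c)) for c in HCIP_COLUMNS
                )
                + "\n"
            )

    edges_path = out / "edges.tsv"
    with open(edges_path, "w") as fh:
        fh.write("bait\tprey\tprovenance\tp_value\tlog2fc\tsinq\n")
        for r in recs:
            if r.passed_filters:
                fh.write(
                    f"{r.bait_id}\t{r.protein_acc}\t{r.provenance}\t"
                    f"{_fmt(r.p_value)}\t{_fmt(r.log2fc)}\t{_fmt(r.sinq_score)}\n"
                )

    summary_path = out / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summaries, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return [hcips_path, edges_path, summary_path]


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_hcips(path: str | Path):
    """Read hcips.tsv back into HcipRecord objects (round-trip of write_outputs)."""
    from .hcip import HcipRecord

    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            HcipRecord(
                bait_id=str(row.bait_id),
                protein_acc=str(row.protein_acc),
                provenance=str(row.provenance),
                p_value=float(row.p_value) if pd.notna(row.p_value) else float("nan"),
                q_value=float(row.q_value) if pd.notna(row.q_value) else float("nan"),
                log2fc=float(row.log2fc) if pd.notna(row.log2fc) else float("nan"),
                unique_peptides=int(row.unique_peptides),
                sinq_score=float(row.sinq_score)
                if pd.notna(row.sinq_score)
                else float("nan"),
                passed_filters=bool(row.passed_filters),
            )
        )
    return records
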