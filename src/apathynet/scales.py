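"""Apathy instrument definitions and cohort dataset input/output.

Three self-report instruments drive every analysis in this package: the
Apathy Motivation Index (AMI, 18 items, a-priori Behavioural / Social /
Emotional domains), the Apathy Evaluation Scale (AES, 18 items) and the
Dimensional Apathy Scale (DAS, 24 items).  Item -> domain keys and
reverse-key flags are shipped as a plain-text registry file
(``data/scale_registry.csv``) rather than hard-coded, so the instrument
keys can be corrected or extended without touching code.

Datasets are participants x items tables of ordinal 0-4 responses with
cohort, age and assessment-mode metadata, read from and written to
delimited text (comma or tab, UTF-8, blank/NA = missing).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "RegistryError",
    "SchemaError",
    "ValidationError",
    "ScaleDefinition",
    "CohortDataset",
    "load_registry",
    "builtin_scale",
    "battery_scale",
    "read_dataset",
    "write_dataset",
    "apply_reverse_keys",
]

#: Domain vocabulary accepted by the registry.
DOMAINS = ("Behavioural", "Social", "Emotional", "Cognitive", "Executive", "Initiation")

#: Metadata columns expected in dataset files, in canonical order.
META_COLUMNS = ("id", "cohort", "age", "mode")


class RegistryError(ValueError):
    """Unknown scale name or malformed registry file."""


class SchemaError(ValueError):
    """Dataset file does not match the scale's expected columns."""


class ValidationError(ValueError):
    """Dataset cell values violate the scale's response range."""


@dataclass(frozen=True)
class ScaleDefinition:
    """An instrument: ordered items, a-priori domains, response range, reverse keys."""

    name: str
    items: tuple[str, ...]
    domain_of: dict[str, str]
    response_min: int = 0
    response_max: int = 4
    reverse_keyed: frozenset[str] = field(default_factory=frozenset)
    stems: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.items)) != len(self.items):
            raise RegistryError(f"duplicate item ids in scale {self.name!r}")
        for item in self.items:
            dom = self.domain_of.get(item)
            if dom is None:
                raise RegistryError(f"item {item!r} has no domain")
            if dom not in DOMAINS:
                raise RegistryError(f"item {item!r} has unknown domain {dom!r}")
        unknown = set(self.reverse_keyed) - set(self.items)
        if unknown:
            raise RegistryError(f"reverse-keyed ids not in scale: {sorted(unknown)}")
        if self.response_max <= self.response_min:
            raise RegistryError("response_max must exceed response_min")

    @property
    def n_items(self) -> int:
        return len(self.items)

    def domains(self) -> tuple[str, ...]:
        """Distinct domains in first-appearance order."""
        seen: list[str] = []
        for item in self.items:
            d = self.domain_of[item]
            if d not in seen:
                seen.append(d)
        return tuple(seen)


def _registry_text() -> str:
    res = importlib.resources.files("apathynet").joinpath("data/scale_registry.csv")
    return res.read_text(encoding="utf-8")


def load_registry() -> pd.DataFrame:
    """Return the shipped item registry (scale, item, domain, reverse, stem)."""
    import io

    df = pd.read_csv(io.StringIO(_registry_text()))
    required = {"scale", "item", "domain", "reverse", "stem"}
    if not required.issubset(df.columns):
        raise RegistryError(f"registry missing columns {sorted(required - set(df.columns))}")
    return df


_EXPECTED_COUNTS = {"AMI": 18, "AES": 18, "DAS": 24}


def builtin_scale(name: str) -> ScaleDefinition:
    """Build one of the three shipped instruments from the registry.

    Raises :class:`RegistryError` for unknown names.  The AMI entry is
    additionally checked against its published shape: 18 items, six each
    in Behavioural, Social and Emotional.
    """
    reg = load_registry()
    rows = reg[reg["scale"] == name]
    if rows.empty:
        raise RegistryError(f"unknown scale {name!r}; expected one of {sorted(_EXPECTED_COUNTS)}")
    scale = ScaleDefinition(
        name=name,
        items=tuple(rows["item"]),
        domain_of=dict(zip(rows["item"], rows["domain"])),
        reverse_keyed=frozenset(rows.loc[rows["reverse"] == 1, "item"]),
        stems=dict(zip(rows["item"], rows["stem"])),
    )
    expected = _EXPECTED_COUNTS.get(name)
    if expected is not None and scale.n_items != expected:
        raise RegistryError(f"registry lists {scale.n_items} items for {name}, expected {expected}")
    if name == "AMI":
        counts = pd.Series([scale.domain_of[i] for i in scale.items]).value_counts()
        for dom in ("Behavioural", "Social", "Emotional"):
            if counts.get(dom, 0) != 6:
                raise RegistryError(f"AMI registry must assign 6 items to {dom}")
    return scale


def battery_scale(names: tuple[str, ...] = ("AMI", "AES", "DAS")) -> ScaleDefinition:
    """Concatenate instruments into one combined battery (e.g. the 60-item set)."""
    parts = [builtin_scale(n) for n in names]
    items: list[str] = []
    domain_of: dict[str, str] = {}
    reverse: set[str] = set()
    stems: dict[str, str] = {}
    for s in parts:
        items.extend(s.items)
        domain_of.update(s.domain_of)
        reverse.update(s.reverse_keyed)
        stems.update(s.stems)
    return ScaleDefinition(
        name="+".join(names),
        items=tuple(items),
        domain_of=domain_of,
        reverse_keyed=frozenset(reverse),
        stems=stems,
    )


@dataclass
class CohortDataset:
    """Participants x items ordinal response table with cohort/age/mode metadata.

    ``responses`` is a float DataFrame (NaN at missing cells) indexed by
    participant id with columns in scale item order; ``missing_mask`` is the
    boolean complement of observedness with the same shape.
    """

    participant_ids: list[str]
    cohort: np.ndarray
    age: np.ndarray
    mode: np.ndarray
    responses: pd.DataFrame
    missing_mask: pd.DataFrame
    scale: ScaleDefinition
    reverse_applied: bool = False

    def __post_init__(self) -> None:
        n = len(self.participant_ids)
        if self.responses.shape != (n, self.scale.n_items):
            raise ValidationError(
                f"responses shape {self.responses.shape} != ({n}, {self.scale.n_items})"
            )
        if tuple(self.responses.columns) != self.scale.items:
            raise SchemaError("response columns must match scale item order")
        if self.missing_mask.shape != self.responses.shape:
            raise ValidationError("missing_mask shape mismatch")
        if np.any(np.asarray(self.age, dtype=float) < 0):
            raise ValidationError("ages must be non-negative")
        vals = self.responses.to_numpy(dtype=float)
        obs = ~self.missing_mask.to_numpy(dtype=bool)
        bad = obs & (
            (vals < self.scale.response_min) | (vals > self.scale.response_max) | np.isnan(vals)
        )
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"response {vals[r, c]!r} out of range "
                f"[{self.scale.response_min}, {self.scale.response_max}] at "
                f"participant {self.participant_ids[r]!r}, item {self.scale.items[c]!r}"
            )

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    def subset(self, mask: np.ndarray) -> "CohortDataset":
        """Row-subset by boolean mask or integer index array."""
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return CohortDataset(
            participant_ids=[self.participant_ids[i] for i in idx],
            cohort=np.asarray(self.cohort)[idx],
            age=np.asarray(self.age)[idx],
            mode=np.asarray(self.mode)[idx],
            responses=self.responses.iloc[idx].copy(),
            missing_mask=self.missing_mask.iloc[idx].copy(),
            scale=self.scale,
            reverse_applied=self.reverse_applied,
        )

    def complete_cases(self) -> "CohortDataset":
        """Listwise deletion: keep participants with no missing responses."""
        keep = ~self.missing_mask.to_numpy(dtype=bool).any(axis=1)
        return self.subset(keep)


def read_dataset(path, scale: ScaleDefinition, sep: str | None = None) -> CohortDataset:
    """Read a delimited-text cohort file and validate it against ``scale``.

    The header must contain ``id``, ``cohort``, ``age`` (``mode`` optional)
    plus one column per scale item, in any order.  Blank or NA cells become
    missing.  Raises :class:`SchemaError` for absent item columns and
    :class:`ValidationError` for out-of-range responses.
    """
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    for col in ("id", "cohort", "age"):
        if col not in df.columns:
            raise SchemaError(f"missing metadata column {col!r}")
    missing_items = [i for i in scale.items if i not in df.columns]
    if missing_items:
        raise SchemaError(f"missing item columns: {missing_items}")

    na_tokens = {"", "NA", "N/A", "NaN", "nan", "None"}
    raw = df.loc[:, list(scale.items)]
    mask = raw.isin(na_tokens) | raw.isna()
    vals = raw.mask(mask)
    try:
        vals = vals.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric response cell: {exc}") from exc
    mode = df["mode"].replace("", "unknown").to_numpy() if "mode" in df.columns else np.full(len(df), "unknown", dtype=object)
    return CohortDataset(
        participant_ids=list(df["id"].astype(str)),
        cohort=df["cohort"].to_numpy(),
        age=df["age"].astype(float).to_numpy(),
        mode=np.asarray(mode, dtype=object),
        responses=vals.set_axis(list(df["id"].astype(str)), axis=0),
        missing_mask=mask.set_axis(list(df["id"].astype(str)), axis=0),
        scale=scale,
    )


def write_dataset(ds: CohortDataset, path, sep: str = ",") -> None:
    """Write a cohort dataset as delimited text (round-trips with :func:`read_dataset`)."""
    out = pd.DataFrame({
        "id": ds.participant_ids,
        "cohort": ds.cohort,
        "age": ds.age,
        "mode": ds.mode,
    })
    resp = ds.responses.reset_index(drop=True)
    # integer responses are written without a decimal point so files round-trip exactly
    for col in resp.columns:
        v = resp[col]
        if np.all(np.isnan(v) | (v == np.floor(v.fillna(0)))):
            out[col] = v.map(lambda x: "" if pd.isna(x) else str(int(x)))
        else:
            out[col] = v.map(lambda x: "" if pd.isna(x) else repr(float(x)))
    out.to_csv(path, sep=sep, index=False)


def apply_reverse_keys(ds: CohortDataset) -> CohortDataset:
    """Flip reverse-keyed items so that higher always means more apathetic.

    ``response <- response_max - response`` for each reverse-keyed item.  The
    transform is recorded on the returned dataset; applying it twice raises,
    because a second application would silently undo the first.
    """
    if ds.reverse_applied:
        raise ValidationError("reverse keys already applied to this dataset")
    resp = ds.responses.copy()
    for item in ds.scale.reverse_keyed:
        resp[item] = ds.scale.response_max - resp[item]
    return replace(ds, responses=resp, reverse_applied=True)
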