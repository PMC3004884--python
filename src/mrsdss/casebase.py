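"""Portable case database: users, cases, spectra, clinical records, notes.

The store mirrors a small relational model — users, cases (each owning
spectra per TE class, a clinical record, notes and image references) and
per-classifier 2D coordinates — persisted as a directory of plain JSON
documents (an index file, one file per case, one coordinates file per
classifier).  Relational semantics (unique ids, ownership) are enforced as
invariants.

Editing rules: every user of an installation can see every case, but only
the uploader (or an administrator) may edit a case's fields; *any* user may
append case notes, which turns the store into a shared knowledge base.
Passwords and authentication are out of scope; users are bare usernames
with an admin flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .spectra_io import CanonicalSpectrum, N_POINTS, TeClass

__all__ = [
    "UserProfile",
    "ClinicalRecord",
    "CaseRecord",
    "CaseStore",
    "PermissionError_",
    "ConflictError",
    "NotFoundError",
]

#: Case sets the system distinguishes; "user" cases start empty on install.
CASE_SETS = ("INTERPRET", "IDI-Bellvitge", "example", "user")


class PermissionError_(PermissionError):
    """The acting user is not allowed to perform this edit."""


class ConflictError(ValueError):
    """An id is already taken."""


class NotFoundError(KeyError):
    """No record with this id."""


@dataclass
class UserProfile:
    username: str
    is_admin: bool = False
    #: glyph display preferences per superclass, e.g. {"aggressive": "red/circle"}
    glyphs: dict[str, str] = field(default_factory=dict)


@dataclass
class ClinicalRecord:
    """Clinical metadata of a case; every field optional."""

    age: int | None = None
    sex: str | None = None
    tumour_location: str | None = None
    tumour_size: str | None = None
    radiological_diagnosis: str | None = None
    total_removal: bool | None = None
    subtotal_removal: bool | None = None
    stereotactic_biopsy: bool | None = None
    who_classification: str | None = None
    daumas_duport_grade: str | None = None
    outcome_3_months: str | None = None
    outcome_2_years: str | None = None
    concomitant_disease: str | None = None
    histopathology_validated: bool | None = None
    localisation_validated: bool | None = None
    assigned_class: str | None = None


@dataclass
class CaseRecord:
    """One patient case: spectra per TE class plus clinical context."""

    case_id: str
    uploader: str | None = None
    tissue_type: str | None = None
    case_set: str = "user"
    spectra: dict[str, list[float]] = field(default_factory=dict)  # te_class -> 512 reals
    clinical: ClinicalRecord = field(default_factory=ClinicalRecord)
    notes: list[dict] = field(default_factory=list)  # {"user":, "text":}
    image_refs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.case_set not in CASE_SETS:
            raise ValueError(f"unknown case set {self.case_set!r}")
        if self.case_set == "user" and not self.uploader:
            raise ValueError("user-set cases must carry an uploader")
        for te, values in self.spectra.items():
            TeClass(te)
            if len(values) != N_POINTS:
                raise ValueError(f"spectrum for TE {te!r} must have {N_POINTS} points")

    def set_spectrum(self, spectrum: CanonicalSpectrum) -> None:
        self.spectra[spectrum.te_class.value] = [float(v) for v in spectrum.intensities]

    def get_spectrum(self, te_class: TeClass | str) -> CanonicalSpectrum:
        te = TeClass(te_class)
        if te.value not in self.spectra:
            raise NotFoundError(f"case {self.case_id}: no {te.value}-TE spectrum")
        return CanonicalSpectrum(np.asarray(self.spectra[te.value]), te)


#: CaseRecord fields any user may touch (none: notes go through add_note).
_NOTE_FIELDS = frozenset({"notes"})


class CaseStore:
    """Directory-backed store of users, cases and classifier coordinates.

    Layout::

        root/
          index.json            users + registered classifiers
          cases/<case_id>.json  one document per case
          coords/<classifier_id>.json  case_id -> [x, y]
    """

    def __init__(self, root: str | Path) -> None:
        self.root = Path(root)
        (self.root / "cases").mkdir(parents=True, exist_ok=True)
        (self.root / "coords").mkdir(parents=True, exist_ok=True)
        self._index_path = self.root / "index.json"
        if self._index_path.exists():
            self._index = json.loads(self._index_path.read_text())
        else:
            self._index = {"users": {}, "classifiers": []}
            self._save_index()

    def _save_index(self) -> None:
        self._index_path.write_text(json.dumps(self._index, indent=1, sort_keys=True))

    # -- users ---------------------------------------------------------------

    def add_user(self, user: UserProfile) -> None:
        if user.username in self._index["users"]:
            raise ConflictError(f"username {user.username!r} already exists")
        self._index["users"][user.username] = {
            "is_admin": user.is_admin,
            "glyphs": user.glyphs,
        }
        self._save_index()

    def get_user(self, username: str) -> UserProfile:
        try:
            entry = self._index["users"][username]
        except KeyError:
            raise NotFoundError(f"no user {username!r}") from None
        return UserProfile(username, entry["is_admin"], dict(entry["glyphs"]))

    def _resolve_user(self, user: UserProfile | str) -> UserProfile:
        return user if isinstance(user, UserProfile) else self.get_user(user)

    # -- cases ---------------------------------------------------------------

    def _case_path(self, case_id: str) -> Path:
        safe = "".join(c if c.isalnum() or c in "-_." else "_" for c in case_id)
        return self.root / "cases" / f"{safe}.json"

    def add_case(self, case: CaseRecord, user: UserProfile | str) -> str:
        """Persist a new case; visible to every user of the installation."""
        user = self._resolve_user(user)
        path = self._case_path(case.case_id)
        if path.exists():
            raise ConflictError(f"case id {case.case_id!r} already exists")
        if case.uploader is None:
            case.uploader = user.username
        payload = asdict(case)
        path.write_text(json.dumps(payload, indent=1))
        return case.case_id

    def get_case(self, case_id: str) -> CaseRecord:
        path = self._case_path(case_id)
        if not path.exists():
            raise NotFoundError(f"no case {case_id!r}")
        data = json.loads(path.read_text())
        clinical = ClinicalRecord(**data.pop("clinical"))
        return CaseRecord(clinical=clinical, **data)

    def edit_case(
        self, case_id: str, patch: dict, user: UserProfile | str
    ) -> CaseRecord:
        """Apply a field patch; only the uploader or an admin may edit.

        ``patch`` maps CaseRecord field names (or ``"clinical.<field>"``)
        to new values.  Appending notes is not an edit: use
        :meth:`add_note`, which any user may call.
        """
        user = self._resolve_user(user)
        case = self.get_case(case_id)
        if user.username != case.uploader and not user.is_admin:
            raise PermissionError_(
                f"user {user.username!r} is not the uploader of case {case_id!r}"
            )
        for key, value in patch.items():
            if key in _NOTE_FIELDS:
                raise ValueError("append notes through add_note()")
            if key.startswith("clinical."):
                fname = key.split(".", 1)[1]
                if not hasattr(case.clinical, fname):
                    raise ValueError(f"unknown clinical field {fname!r}")
                setattr(case.clinical, fname, value)
            elif hasattr(case, key) and key not in ("case_id", "uploader"):
                setattr(case, key, value)
            else:
                raise ValueError(f"unknown or immutable field {key!r}")
        # re-validate invariants before persisting
        case = CaseRecord(**{**asdict(case), "clinical": case.clinical})
        self._case_path(case_id).write_text(json.dumps(asdict(case), indent=1))
        return case

    def add_note(self, case_id: str, text: str, user: UserProfile | str) -> CaseRecord:
        """Append a shared case note — allowed for every user."""
        user = self._resolve_user(user)
        case = self.get_case(case_id)
        case.notes.append({"user": user.username, "text": text})
        self._case_path(case_id).write_text(json.dumps(asdict(case), indent=1))
        return case

    def list_cases(
        self,
        case_set: str | None = None,
        superclass: str | None = None,
        te_available: str | None = None,
    ) -> list[CaseRecord]:
        """All cases matching the filters, ordered by case id."""
        out = []
        for path in sorted((self.root / "cases").glob("*.json")):
            case = CaseRecord(
                **{
                    **(d := json.loads(path.read_text())),
                    "clinical": ClinicalRecord(**d["clinical"]),
                }
            )
            if case_set is not None and case.case_set != case_set:
                continue
            if superclass is not None and case.tissue_type != superclass:
                continue
            if te_available is not None and te_available not in case.spectra:
                continue
            out.append(case)
        out.sort(key=lambda c: c.case_id)
        return out

    # -- classifiers & coordinates --------------------------------------------

    def register_classifier(self, classifier_id: str) -> None:
        if classifier_id not in self._index["classifiers"]:
            self._index["classifiers"].append(classifier_id)
            self._save_index()

    def store_coordinates(
        self, classifier_id: str, projections: dict[str, tuple[float, float]]
    ) -> int:
        """Upsert per-case 2D latent coordinates for a registered classifier."""
        if classifier_id not in self._index["classifiers"]:
            raise NotFoundError(f"classifier {classifier_id!r} not registered")
        path = self.root / "coords" / f"{classifier_id}.json"
        existing = json.loads(path.read_text()) if path.exists() else {}
        for case_id, (x, y) in projections.items():
            existing[case_id] = [float(x), float(y)]
        path.write_text(json.dumps(existing, indent=1, sort_keys=True))
        return len(existing)

    def get_coordinates(self, classifier_id: str) -> dict[str, tuple[float, float]]:
        path = self.root / "coords" / f"{classifier_id}.json"
        if not path.exists():
            if classifier_id not in self._index["classifiers"]:
                raise NotFoundError(f"classifier {classifier_id!r} not registered")
            return {}
        data = json.loads(path.read_text())
        return {k: (v[0], v[1]) for k, v in data.items()}
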