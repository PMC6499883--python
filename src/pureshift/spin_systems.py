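"""Metabolite spin-system definitions for aqueous fruit-extract ¹H spectra.

A metabolite is a set of proton groups, each with a chemical shift (ppm,
referenced to TSP = 0), an equivalent-proton count and a list of scalar
couplings to partner groups within the same molecule.  The default library
covers the constituents of Cape-gooseberry (*Physalis peruviana*) aqueous
extracts whose shifts are published; coupling constants are
literature-typical fixtures (solution ¹H couplings are rarely tabulated to
the precision shifts are) and are freely editable through the YAML
round-trip below.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

#: Plausible ¹H chemical-shift window (ppm) for aqueous metabolite spectra.
SHIFT_WINDOW = (-0.5, 10.0)


@dataclass(frozen=True)
class ProtonGroup:
    """A set of chemically equivalent protons.

    Parameters
    ----------
    label : str
        Group label, unique within its metabolite (e.g. ``"Halpha"``).
    shift_ppm : float
        Chemical shift relative to TSP = 0 ppm.
    n_equiv : int
        Number of equivalent protons (≥ 1).
    couplings : tuple of (str, float)
        ``(partner label, J in Hz)`` scalar couplings to other groups of the
        same metabolite.  The relation must be symmetric: if A lists B at J,
        B must list A at the same J.
    """

    label: str
    shift_ppm: float
    n_equiv: int = 1
    couplings: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "couplings", tuple((str(p), float(j)) for p, j in self.couplings))


@dataclass(frozen=True)
class Metabolite:
    """Named collection of proton groups forming one spin system."""

    name: str
    groups: tuple[ProtonGroup, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))

    def group(self, label: str) -> ProtonGroup:
        for g in self.groups:
            if g.label == label:
                return g
        raise KeyError(f"{self.name}: no proton group {label!r}")

    @property
    def n_protons(self) -> int:
        return sum(g.n_equiv for g in self.groups)


class MetaboliteLibrary:
    """Mapping of metabolite name -> :class:`Metabolite`."""

    def __init__(self, metabolites: list[Metabolite] | tuple[Metabolite, ...] = ()):
        self._by_name: dict[str, Metabolite] = {}
        for m in metabolites:
            self.add(m)

    def add(self, m: Metabolite) -> None:
        if m.name in self._by_name:
            raise ValueError(f"duplicate metabolite name {m.name!r}")
        self._by_name[m.name] = m

    def lookup(self, name: str) -> Metabolite:
        return self._by_name[name]

    def __getitem__(self, name: str) -> Metabolite:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)

    @property
    def names(self) -> list[str]:
        return list(self._by_name)

    def subset(self, names) -> "MetaboliteLibrary":
        return MetaboliteLibrary([self._by_name[n] for n in names])


def validate_library(lib: MetaboliteLibrary) -> list[str]:
    """Check every spin-system invariant; return human-readable violations.

    Rules: shifts inside :data:`SHIFT_WINDOW`; J ≥ 0; n_equiv ≥ 1; group
    labels unique within a metabolite; coupling partners exist; the coupling
    relation is symmetric (same J both ways, tolerance 1e-9 Hz).
    """
    lo, hi = SHIFT_WINDOW
    out: list[str] = []
    for m in lib:
        labels = [g.label for g in m.groups]
        if len(labels) != len(set(labels)):
            out.append(f"{m.name}: duplicate group labels")
        by_label = {g.label: g for g in m.groups}
        for g in m.groups:
            if not (lo <= g.shift_ppm <= hi):
                out.append(f"{m.name}/{g.label}: shift {g.shift_ppm} ppm outside [{lo}, {hi}]")
            if g.n_equiv < 1:
                out.append(f"{m.name}/{g.label}: n_equiv {g.n_equiv} < 1")
            for partner, j in g.couplings:
                if j < 0:
                    out.append(f"{m.name}/{g.label}: negative J {j} to {partner}")
                if partner not in by_label:
                    out.append(f"{m.name}/{g.label}: unknown coupling partner {partner!r}")
                    continue
                back = dict(by_label[partner].couplings)
                if g.label not in back:
                    out.append(f"{m.name}/{g.label}: coupling to {partner} not reciprocated")
                elif abs(back[g.label] - j) > 1e-9:
                    out.append(
                        f"{m.name}/{g.label}: asymmetric J to {partner} ({j} vs {back[g.label]})"
                    )
    return out


def _met(name: str, groups: list[tuple]) -> Metabolite:
    return Metabolite(name, tuple(ProtonGroup(lbl, s, n, tuple(c)) for lbl, s, n, c in groups))


def default_library() -> MetaboliteLibrary:
    """Cape-gooseberry extract spin-system library.

    Chemical shifts of the published resonances are verbatim (sucrose 5.40 /
    4.04, α-glucose 5.23, β-glucose 3.24, β-fructose 4.02 / 3.99, proline
    4.13 / 3.41 / 3.33 / 2.34 / 2.07 / 2.00, glutamic acid 2.16 / 2.44,
    glutamine 2.13, GABA 3.03, malic acid 4.41 / 2.82 / 2.67, asparagine
    3.97, myo-inositol 3.27, citric acid 2.75 / 2.87).  All J constants, and
    shifts of groups without a published value, are literature-typical
    fixtures, not measured values.
    """
    mets = [
        _met("sucrose", [
            ("H1g", 5.40, 1, [("H2g", 3.9)]),
            ("H2g", 3.55, 1, [("H1g", 3.9)]),
            ("H3f", 4.21, 1, [("H4f", 8.7)]),
            ("H4f", 4.04, 1, [("H3f", 8.7)]),
        ]),
        _met("alpha-glucose", [
            ("H1", 5.23, 1, [("H2", 3.8)]),
            ("H2", 3.52, 1, [("H1", 3.8), ("H3", 9.7)]),
            ("H3", 3.70, 1, [("H2", 9.7)]),
        ]),
        _met("beta-glucose", [
            ("H1", 4.64, 1, [("H2", 8.0)]),
            ("H2", 3.24, 1, [("H1", 8.0), ("H3", 9.3)]),
            ("H3", 3.48, 1, [("H2", 9.3)]),
        ]),
        _met("beta-fructose", [
            ("H3", 4.02, 1, [("H4", 8.8)]),
            ("H4", 3.99, 1, [("H3", 8.8)]),
        ]),
        _met("proline", [
            ("Halpha", 4.13, 1, [("Hbeta", 6.3), ("Hbeta2", 8.6)]),
            ("Hdelta", 3.41, 1, [("Hdelta2", 11.7), ("Hgamma", 6.0)]),
            ("Hdelta2", 3.33, 1, [("Hdelta", 11.7)]),
            ("Hbeta", 2.34, 1, [("Halpha", 6.3), ("Hbeta2", 13.0)]),
            ("Hgamma", 2.07, 2, [("Hdelta", 6.0)]),
            ("Hbeta2", 2.00, 1, [("Halpha", 8.6), ("Hbeta", 13.0)]),
        ]),
        _met("glutamic acid", [
            ("Hbeta", 2.16, 2, [("Hgamma", 7.5)]),
            ("Hgamma", 2.44, 2, [("Hbeta", 7.5)]),
        ]),
        _met("glutamine", [
            ("Hbeta", 2.13, 2, [("Hgamma", 7.6)]),
            ("Hgamma", 2.46, 2, [("Hbeta", 7.6)]),
        ]),
        _met("GABA", [
            ("H4", 3.03, 2, [("H3", 7.3)]),
            ("H2", 2.30, 2, [("H3", 7.3)]),
            ("H3", 1.90, 2, [("H4", 7.3), ("H2", 7.3)]),
        ]),
        _met("malic acid", [
            ("Halpha", 4.41, 1, [("Hbeta", 3.1), ("Hbeta2", 10.0)]),
            ("Hbeta", 2.82, 1, [("Halpha", 3.1), ("Hbeta2", 15.5)]),
            ("Hbeta2", 2.67, 1, [("Halpha", 10.0), ("Hbeta", 15.5)]),
        ]),
        _met("asparagine", [
            ("Halpha", 3.97, 1, [("Hbeta", 4.3), ("Hbeta2", 7.6)]),
            ("Hbeta", 2.94, 1, [("Halpha", 4.3), ("Hbeta2", 16.9)]),
            ("Hbeta2", 2.85, 1, [("Halpha", 7.6), ("Hbeta", 16.9)]),
        ]),
        _met("myo-inositol", [
            ("H5", 3.27, 1, [("H46", 9.3)]),
            ("H46", 3.61, 2, [("H5", 9.3)]),
            ("H2", 4.06, 1, []),
        ]),
        _met("citric acid", [
            ("Ha", 2.87, 2, [("Hb", 15.9)]),
            ("Hb", 2.75, 2, [("Ha", 15.9)]),
        ]),
        _met("alanine", [
            ("Halpha", 3.78, 1, [("Hbeta", 7.2)]),
            ("Hbeta", 1.48, 3, [("Halpha", 7.2)]),
        ]),
    ]
    lib = MetaboliteLibrary(mets)
    problems = validate_library(lib)
    if problems:  # pragma: no cover - shipped library is valid
        raise AssertionError("default library invalid: " + "; ".join(problems))
    return lib


# ---------------------------------------------------------------------------
# YAML round-trip


def library_to_dict(lib: MetaboliteLibrary) -> dict:
    return {
        m.name: {
            "groups": [
                {
                    "label": g.label,
                    "shift_ppm": g.shift_ppm,
                    "n_equiv": g.n_equiv,
                    "couplings": [{"partner": p, "J_hz": j} for p, j in g.couplings],
                }
                for g in m.groups
            ]
        }
        for m in lib
    }


def library_from_dict(d: dict) -> MetaboliteLibrary:
    mets = []
    for name, spec in d.items():
        groups = tuple(
            ProtonGroup(
                g["label"],
                float(g["shift_ppm"]),
                int(g.get("n_equiv", 1)),
                tuple((c["partner"], float(c["J_hz"])) for c in g.get("couplings", [])),
            )
            for g in spec["groups"]
        )
        mets.append(Metabolite(name, groups))
    return MetaboliteLibrary(mets)


def save_library(lib: MetaboliteLibrary, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(library_to_dict(lib), fh, sort_keys=False)


def load_library(path) -> MetaboliteLibrary:
    with open(path) as fh:
        return library_from_dict(yaml.safe_load(fh))
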