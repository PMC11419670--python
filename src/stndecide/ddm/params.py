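"""Parameter containers for the collapsing-bound drift-diffusion model.

The base model has eight parameters, organized in six groups:

========  =====================================================  =========
group     meaning                                                unit
========  =====================================================  =========
a         maximal bound height                                   DV units
bound     ``b_collapse`` (decay speed) and ``b_t`` (onset) of    1/s, s
          the bound collapse
k         drift scale: drift = k * (signed_coh + me)             DV/s per
                                                                 unit coh
me        momentary-evidence bias                                coherence
z         starting-point offset of the decision variable          DV units
t0        non-decision times ``t0_contra``, ``t0_ipsi``          s
========  =====================================================  =========

Microstimulation effects are additive deltas on these parameters, applied
on stimulated trials only.  Model variants differ in which parameter
groups are allowed a nonzero delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

__all__ = [
    "PARAM_NAMES",
    "PARAM_GROUPS",
    "DDMParams",
    "DDMEffect",
    "VariantSpec",
    "VARIANTS",
]

#: Canonical order of the eight base parameters.
PARAM_NAMES = (
    "a",
    "b_collapse",
    "b_t",
    "k",
    "me",
    "z",
    "t0_contra",
    "t0_ipsi",
)

#: The six parameter groups used by the reduced model variants.
PARAM_GROUPS = {
    "a": ("a",),
    "bound": ("b_collapse", "b_t"),
    "k": ("k",),
    "me": ("me",),
    "z": ("z",),
    "t0": ("t0_contra", "t0_ipsi"),
}


@dataclass(frozen=True)
class DDMParams:
    """Eight base parameters of the collapsing-bound DDM.

    The diffusion SD ``sigma`` is fixed at 1 by the usual scaling
    convention; it is exposed for tests that exercise analytic limits.
    """

    a: float = 1.0
    b_collapse: float = 0.0
    b_t: float = 0.0
    k: float = 6.0
    me: float = 0.0
    z: float = 0.0
    t0_contra: float = 0.3
    t0_ipsi: float = 0.3
    sigma: float = 1.0

    def __post_init__(self):
        if not self.a > 0:
            raise ValueError(f"bound height a must be > 0, got {self.a}")
        if not abs(self.z) < self.a:
            raise ValueError(f"|z| must be < a, got z={self.z}, a={self.a}")
        if self.b_collapse < 0:
            raise ValueError("b_collapse must be >= 0")
        if self.b_t < 0:
            raise ValueError("b_t must be >= 0")
        if self.t0_contra < 0 or self.t0_ipsi < 0:
            raise ValueError("non-decision times must be >= 0")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")

    def is_valid(self) -> bool:
        return (
            self.a > 0
            and abs(self.z) < self.a
            and self.b_collapse >= 0
            and self.b_t >= 0
            and self.t0_contra >= 0
            and self.t0_ipsi >= 0
        )

    def with_effect(self, effect: "DDMEffect | None") -> "DDMParams":
        """Parameters on a stimulated trial: base + additive deltas.

        Raises ``ValueError`` if the shifted parameters violate the base
        invariants (callers that need an optimizer-friendly contract
        should pre-check with :meth:`DDMEffect.shift_is_valid`).
        """
        if effect is None:
            return self
        return replace(
            self,
            **{name: getattr(self, name) + getattr(effect, "d_" + name) for name in PARAM_NAMES},
        )

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class DDMEffect:
    """Additive microstimulation deltas for each base parameter."""

    d_a: float = 0.0
    d_b_collapse: float = 0.0
    d_b_t: float = 0.0
    d_k: float = 0.0
    d_me: float = 0.0
    d_z: float = 0.0
    d_t0_contra: float = 0.0
    d_t0_ipsi: float = 0.0

    @classmethod
    def zero(cls) -> "DDMEffect":
        return cls()

    def masked(self, free_groups: tuple) -> "DDMEffect":
        """Return a copy with deltas outside ``free_groups`` set to 0."""
        free_names = {n for g in free_groups for n in PARAM_GROUPS[g]}
        return DDMEffect(
            **{
                "d_" + name: (getattr(self, "d_" + name) if name in free_names else 0.0)
                for name in PARAM_NAMES
            }
        )

    def shift_is_valid(self, params: DDMParams) -> bool:
        """Whether params + deltas still satisfy the base invariants."""
        a = params.a + self.d_a
        return (
            a > 0
            and abs(params.z + self.d_z) < a
            and params.b_collapse + self.d_b_collapse >= 0
            and params.b_t + self.d_b_t >= 0
            and params.t0_contra + self.d_t0_contra >= 0
            and params.t0_ipsi + self.d_t0_ipsi >= 0
        )

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class VariantSpec:
    """A microstimulation-effect model variant.

    ``free_groups`` lists the parameter groups whose deltas are free.
    The Full variant frees all six groups (8 deltas); None frees none;
    each reduced variant ``NoX`` frees every group except ``X``.
    """

    name: str
    free_groups: tuple = ()

    @property
    def free_param_names(self) -> tuple:
        return tuple(n for g in self.free_groups for n in PARAM_GROUPS[g])

    @property
    def n_free_deltas(self) -> int:
        return len(self.free_param_names)

    @property
    def n_free_params(self) -> int:
        """Free parameters of the fit: 8 base + the variant's free deltas."""
        return len(PARAM_NAMES) + self.n_free_deltas


_ALL = tuple(PARAM_GROUPS)

#: The eight model variants, keyed by name.
VARIANTS = {
    "Full": VariantSpec("Full", _ALL),
    "None": VariantSpec("None", ()),
    "NoA": VariantSpec("NoA", tuple(g for g in _ALL if g != "a")),
    "NoCollapse": VariantSpec("NoCollapse", tuple(g for g in _ALL if g != "bound")),
    "NoK": VariantSpec("NoK", tuple(g for g in _ALL if g != "k")),
    "NoME": VariantSpec("NoME", tuple(g for g in _ALL if g != "me")),
    "NoZ": VariantSpec("NoZ", tuple(g for g in _ALL if g != "z")),
    "NoT": VariantSpec("NoT", tuple(g for g in _ALL if g != "t0")),
}

#: Reduced-variant name for each parameter group.
GROUP_TO_REDUCED = {
    "a": "NoA",
    "bound": "NoCollapse",
    "k": "NoK",
    "me": "NoME",
    "z": "NoZ",
    "t0": "NoT",
}
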