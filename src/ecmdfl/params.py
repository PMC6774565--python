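"""Physical parameter defaults (units: micrometres, seconds, nanonewtons).

These values define the reduced "desk-scale" study conditions used by the
fixture generator.  Every default is overridable through
:class:`ecmdfl.config.SimulationConfig.params`.
"""

from dataclasses import dataclass, field, asdict


@dataclass
class PhysicalParams:
    """Bundle of tunable physical constants for the cell--ECM system.

    Attributes
    ----------
    k_axial : axial (stretch) stiffness of one fiber segment, nN/um.
    k_bend : discrete bending stiffness at interior fiber nodes, nN*um.
    k_cross : stiffness of crosslink springs joining distinct fibers, nN/um.
    D_e : ECM nodal damping coefficient, nN*s/um.
    D_c : cell-membrane nodal damping coefficient, nN*s/um.
    k_edge : membrane edge-spring stiffness, nN/um.
    gamma : isotropic cortical tension (force per unit area gradient), nN/um^2.
    k_fa : focal-adhesion spring stiffness per bound integrin, nN/um.
    n_int : bound integrins per adhesion (fixed multiplicity).
    d_bind : attachment distance for new adhesions, um.
    d_break : detachment distance for existing adhesions, um.
    p_on : per-step attachment probability for an eligible pair.
    f_L : lamellipodial force magnitude per loaded membrane node, nN.
    alpha_L : half apex angle of the leading-edge cone, rad.
    kappa : polarity rotation rate toward the max-stiffness direction, 1/s.
    sensing_radius : radius of the stiffness-sensing neighbourhood, um.
    cell_radius : rest radius of the membrane mesh, um.
    """

    k_axial: float = 2.0
    k_bend: float = 0.1
    k_cross: float = 2.0
    D_e: float = 10.0
    D_c: float = 10.0
    k_edge: float = 1.0
    gamma: float = 0.2
    k_fa: float = 0.5
    n_int: int = 10
    d_bind: float = 4.0
    d_break: float = 10.0
    p_on: float = 0.5
    f_L: float = 1.0
    alpha_L: float = 1.0471975511965976  # pi/3
    kappa: float = 0.002
    sensing_radius: float = 15.0
    cell_radius: float = 6.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhysicalParams":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown physical parameters: {sorted(unknown)}")
        return cls(**d)
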