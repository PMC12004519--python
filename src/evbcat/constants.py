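"""Physical constants, repository-wide units: kcal/mol, Å, K, elementary charge."""

#: Gas constant, kcal mol^-1 K^-1.
R_KCAL: float = 1.9872e-3

#: Boltzmann constant over Planck constant, s^-1 K^-1 (Eyring prefactor per kelvin).
KB_OVER_H: float = 2.08366e10

#: Coulomb constant, kcal Å mol^-1 e^-2.
COULOMB_CONST: float = 332.0636

#: Seconds per minute, exact (rate unit conversion).
S_PER_MIN: float = 60.0


def rt(temperature: float) -> float:
    """Thermal energy R*T in kcal/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KCAL * temperature
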