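from hypothesis import settings

from mrkit.instruments import HarmonisedInstrument

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_instruments(beta_x, beta_y, se_y, se_x=None):
    """Build a harmonised instrument list from parallel effect arrays."""
    if se_x is None:
        se_x = [0.01] * len(beta_x)
    return [
        HarmonisedInstrument.from_effects(f"rs{i + 1:03d}", bx, sx, by, sy)
        for i, (bx, sx, by, sy) in enumerate(zip(beta_x, se_x, beta_y, se_y))
    ]
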