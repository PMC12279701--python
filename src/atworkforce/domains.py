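"""The five assistive-product domains used throughout the package.

Provision systems are organised around product domains that largely mirror
domains of human functioning.  Ordinary spectacles are excluded from the
vision domain because they are supplied through a separate provisioning
system.
"""

DOMAINS: tuple[str, ...] = (
    "cognition_communication",
    "hearing",
    "mobility_selfcare",
    "orthotics_prosthetics",
    "vision",
)

DOMAIN_LABELS: dict[str, str] = {
    "cognition_communication": "Cognition and communication",
    "hearing": "Hearing",
    "mobility_selfcare": "Mobility and self-care",
    "orthotics_prosthetics": "Orthotics and prosthetics",
    "vision": "Vision",
}


def check_domain(domain: str) -> str:
    if domain not in DOMAINS:
        raise ValueError(f"unknown product domain {domain!r}; expected one of {DOMAINS}")
    return domain
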