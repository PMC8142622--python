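"""Bundled sampling pools for the synthetic registry generator.

The pools are small frequency-ordered lists of common Brazilian given
names, surnames and name particles, plus ~100 IBGE-style seven-digit
municipality codes.  They are deliberately compact: the goal is to
reproduce the *structural* features real linkage must cope with —
accented characters, DA/DE/DOS particles, heavy surname reuse — not to
be demographically representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

GIVEN_NAMES_F: tuple[str, ...] = (
    "Maria", "Ana", "Francisca", "Antônia", "Adriana", "Juliana", "Márcia",
    "Fernanda", "Patrícia", "Aline", "Sandra", "Camila", "Amanda", "Bruna",
    "Jéssica", "Letícia", "Júlia", "Luciana", "Vanessa", "Mariana",
    "Gabriela", "Vera", "Vitória", "Larissa", "Cláudia", "Beatriz", "Rita",
    "Luana", "Sônia", "Renata", "Eliane", "Raimunda", "Rosângela", "Simone",
    "Daniela", "Tereza", "Cristiane", "Luzia", "Débora", "Elaine", "Carla",
    "Tatiane", "Michele", "Josefa", "Regina", "Severina", "Aparecida",
    "Fátima", "Isabel", "Conceição", "Lúcia", "Helena", "Sueli", "Rosa",
    "Iracema", "Marlene", "Terezinha", "Edna", "Neide", "Zilda",
)

GIVEN_NAMES_M: tuple[str, ...] = (
    "José", "João", "Antônio", "Francisco", "Carlos", "Paulo", "Pedro",
    "Lucas", "Luiz", "Marcos", "Luís", "Gabriel", "Rafael", "Daniel",
    "Marcelo", "Bruno", "Eduardo", "Felipe", "Raimundo", "Rodrigo",
    "Manoel", "Mateus", "André", "Fernando", "Fábio", "Leonardo",
    "Gustavo", "Guilherme", "Leandro", "Tiago", "Sebastião", "Alexandre",
    "Ricardo", "Jorge", "Sérgio", "Cláudio", "Geraldo", "Adriano",
    "Márcio", "Júlio", "Renato", "Anderson", "Róbson", "Vinícius",
    "Severino", "Diego", "Alex", "Jefferson", "Mauro", "Válter",
    "Joaquim", "Benedito", "Osvaldo", "Expedito", "Valdir", "Gilberto",
    "Cícero", "Edson", "Wellington", "Otávio",
)

SURNAMES: tuple[str, ...] = (
    "Silva", "Santos", "Oliveira", "Souza", "Rodrigues", "Ferreira",
    "Alves", "Pereira", "Lima", "Gomes", "Ribeiro", "Carvalho", "Almeida",
    "Lopes", "Soares", "Fernandes", "Vieira", "Barbosa", "Rocha", "Dias",
    "Nascimento", "Andrade", "Moreira", "Nunes", "Marques", "Machado",
    "Mendes", "Freitas", "Cardoso", "Ramos", "Gonçalves", "Santana",
    "Teixeira", "Araújo", "Costa", "Martins", "Melo", "Cavalcanti",
    "Correia", "Cunha", "Pinto", "Monteiro", "Moura", "Barros", "Campos",
    "Farias", "Batista", "Azevedo", "Conceição", "Jesus", "Reis",
    "Miranda", "Duarte", "Aragão", "Tavares", "Medeiros", "Brito",
    "Xavier", "Sales", "Magalhães",
)

#: Linking particles kept (not stripped) by the default normalizer.
PARTICLES: tuple[str, ...] = ("da", "de", "do", "das", "dos", "e")

#: IBGE-style seven-digit municipality codes (state prefix + sequence +
#: check digit); a ~100-code subset spanning all regions.
MUNICIPALITY_CODES: tuple[str, ...] = (
    "1100205", "1200401", "1302603", "1400100", "1501402", "1600303",
    "1721000", "2111300", "2211001", "2304400", "2408102", "2507507",
    "2611606", "2704302", "2800308", "2927408", "3106200", "3205309",
    "3304557", "3550308", "4106902", "4205407", "4314902", "5002704",
    "5103403", "5208707", "5300108", "2910800", "2919207", "2905701",
    "2929206", "2930501", "2918407", "2925303", "2910057", "2933307",
    "3509502", "3518800", "3543402", "3548708", "3552205", "3525904",
    "3534401", "3513801", "3529401", "3547809", "3301702", "3303500",
    "3304904", "3302858", "3303302", "3305109", "3136702", "3170206",
    "3118601", "3143302", "3127701", "3162500", "2609600", "2604106",
    "2607901", "2610707", "2613909", "2307650", "2312908", "2303709",
    "2307304", "2128600", "2105302", "2103000", "4113700", "4115200",
    "4119905", "4108304", "4209102", "4216602", "4202404", "4305108",
    "4316907", "4304606", "4313409", "5201405", "5213087", "5218805",
    "1501709", "1502400", "1506807", "1100122", "1304062", "5107602",
    "5102504", "5006200", "5003702", "2800605", "2802106", "1600600",
    "1721208", "2408003", "2510808", "2704708",
)


@dataclass(frozen=True)
class NamePools:
    """Sampling pools handed to the registry generator."""

    given_f: tuple[str, ...] = GIVEN_NAMES_F
    given_m: tuple[str, ...] = GIVEN_NAMES_M
    surnames: tuple[str, ...] = SURNAMES
    particles: tuple[str, ...] = PARTICLES
    municipality_codes: tuple[str, ...] = MUNICIPALITY_CODES

    def __post_init__(self) -> None:
        for name in ("given_f", "given_m", "surnames", "municipality_codes"):
            if not getattr(self, name):
                raise ValueError(f"pool {name!r} must be non-empty")


DEFAULT_POOLS = NamePools()
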