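import pytest

from paincorpus import SyntheticConfig, default_gazetteers, default_lexicon, generate_corpus

# The six worked annotation examples: sentence, keyword surface, and the
# five expected labels (correct, relevance, anatomy, character, management).
ANNOTATION_EXAMPLES = [
    ("He likes burning things", "burning",
     ("no", "n/a", "n/a", "n/a", "n/a")),
    ("She painted a picture of the situation", "painted",
     ("no", "n/a", "n/a", "n/a", "n/a")),
    ("She is in constant pain", "pain",
     ("yes", "relevant", "n/a", "other", "n/a")),
    ("He suffers from severe headaches", "headaches",
     ("yes", "relevant", "mentioned", "other", "n/a")),
    ("He is not on painkillers", "painkillers",
     ("yes", "negated", "n/a", "n/a", "medication")),
    ("Afraid I will be in pain if surgery is unsuccessful", "pain",
     ("yes", "not_relevant", "n/a", "n/a", "n/a")),
]

# Each shipped wildcard row with its printed example words.
WILDCARD_EXAMPLES = [
    ("%pain%", "Pain", ["pains", "painful"]),
    ("%ache", "Ache", ["headache", "backache"]),
    ("%aches", "Ache", ["headaches", "aches"]),
    ("sore%", "Sore", ["soreness", "sores"]),
    ("%algesi%", "Algesia", ["analgesia", "analgesic"]),
    ("%algia%", "Algia", ["proctalgia", "neuralgias"]),
    ("%burn%", "Burn", ["heartburn", "burns", "burning"]),
    ("colic%", "Colic", ["colicky"]),
    ("cramp%", "Cramp", ["cramps", "cramping"]),
    ("%dynia%", "Dynia", ["allodynia", "glossodynia"]),
    ("hurt%", "Hurt", ["hurts", "hurting"]),
    ("rheumati%", "Rheumatic", ["rheumatic", "rheumatism"]),
    ("sciati%", "Sciatic", ["sciatic", "sciatica"]),
    ("spasm%", "Spasm", ["spasms", "spasmic"]),
    ("tender%", "Tender", ["tenderness"]),
]


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def gazetteers():
    return default_gazetteers()


@pytest.fixture(scope="session")
def small_corpus():
    """A small seeded gold corpus shared across tests (~250 mentions)."""
    return generate_corpus(SyntheticConfig(seed=11, n_patients=30))


@pytest.fixture(scope="session")
def default_scale_corpus():
    """A default-mixture corpus large enough for distribution checks."""
    return generate_corpus(SyntheticConfig(seed=23, n_patients=250))
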