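"""Bundled French-like clinical word pool for the synthetic terminology.

The pool mixes accented and plain forms on purpose: real problem-list
labels carry accents that lie outside the query alphabet, so generated
terminologies exercise the accent-folding normalization path.
"""

#: Content words used to compose label texts.
WORDS = (
    "hypertension", "artérielle", "pulmonaire", "portale",
    "diabète", "insuffisance", "cardiaque", "rénale", "hépatique",
    "respiratoire", "chronique", "aiguë", "infection", "urinaire",
    "voies", "respiratoires", "supérieures", "pneumonie", "bactérienne",
    "virale", "fracture", "fémur", "poignet", "douleur", "thoracique",
    "abdominale", "lombaire", "céphalée", "tension", "migraine",
    "asthme", "bronchite", "embolie", "thrombose", "veineuse", "profonde",
    "anémie", "ferriprive", "carence", "vitamine", "dépression",
    "anxiété", "trouble", "sommeil", "apnée", "obstructive", "obésité",
    "morbide", "hypothyroïdie", "hyperthyroïdie", "gastrite", "ulcère",
    "gastrique", "duodénal", "hépatite", "cirrhose", "alcoolique",
    "pancréatite", "colique", "néphrétique", "calcul", "rénal",
    "cystite", "prostatite", "arthrose", "genou", "hanche", "épaule",
    "polyarthrite", "rhumatoïde", "ostéoporose", "accident", "vasculaire",
    "cérébral", "ischémique", "hémorragique", "transitoire", "épilepsie",
    "focale", "généralisée", "sclérose", "plaques", "maladie",
    "parkinson", "démence", "alzheimer", "carcinome", "pancréas",
    "poumon", "sein", "côlon", "prostate", "mélanome", "cutané",
    "lymphome", "leucémie", "myélome", "insomnie", "vertige", "syncope",
    "palpitations", "fibrillation", "auriculaire", "valvulopathie",
    "sténose", "aortique", "mitrale", "dermatite", "atopique",
    "psoriasis", "eczéma", "urticaire", "allergie", "pollen", "rhinite",
    "allergique", "sinusite", "otite", "moyenne", "angine", "grippe",
    "saisonnière", "séquelle", "plaie", "cheville", "entorse",
    "luxation", "tendinite", "hernie", "discale", "inguinale",
    "appendicite", "péritonite", "occlusion", "intestinale",
    "constipation", "diarrhée", "gastroentérite", "déshydratation",
    "hypoglycémie", "goutte", "hypercholestérolémie", "bronchopneumopathie",
    "obstructive", "rétrosternale", "oedème", "membre", "inférieur",
)

#: Qualifier tails appended to a base label to form family variants
#: ("hypertension artérielle" → "hypertension artérielle sévère").
QUALIFIERS = (
    "sévère", "modérée", "légère", "chronique", "aiguë", "compliquée",
    "récidivante", "bilatérale", "gauche", "droite", "stade 2", "grade 3",
    "décompensée", "stable", "instable", "traitée", "secondaire",
    "primaire", "familiale", "débutante",
)
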