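# Curated chronic-condition classification of ICD-10 codes at 3-digit
# granularity.  A 3-digit category is listed here when the condition (or any
# of its 4-character children) is a chronic condition, i.e. one not expected
# to resolve within a single hospitalization episode.  Ranges are inclusive
# and must stay within one letter prefix.  Lines starting with '#' are
# comments; inline comments after whitespace are allowed.
#
# This file is a package default and is fully overridable: pass a custom
# file to ChronicMap.from_file or edit in place.

# Chapter I — chronic infections
A15-A19   # tuberculosis
A30       # leprosy
A31       # other mycobacterial infection
B18       # chronic viral hepatitis
B20-B24   # HIV disease
B90-B94   # sequelae of infectious diseases

# Chapter II — malignant neoplasms (all treated as chronic)
C00-C97

# Chapter III — blood and immune disorders
D50-D53   # nutritional anemias
D55-D64   # hemolytic, aplastic and other anemias
D66-D69   # coagulation defects and purpura
D70       # agranulocytosis
D71-D77   # other blood/blood-forming organ diseases
D80-D89   # immune mechanism disorders

# Chapter IV — endocrine, nutritional and metabolic
E00-E07   # thyroid disorders
E10-E14   # diabetes mellitus
E15-E16   # other glucose regulation disorders
E20-E35   # other endocrine gland disorders
E40-E46   # malnutrition
E50-E64   # other nutritional deficiencies
E65-E68   # obesity and hyperalimentation
E70-E90   # metabolic disorders

# Chapter V — mental and behavioural
F00-F09   # organic mental disorders
F10-F19   # psychoactive substance use
F20-F29   # schizophrenia and delusional disorders
F30-F39   # mood disorders
F40-F48   # neurotic and stress-related disorders
F60-F69   # personality disorders
F70-F79   # mental retardation
F80-F89   # psychological development disorders
F90-F99

# Chapter VI — nervous system
G10-G14   # systemic atrophies
G20-G26   # extrapyramidal and movement disorders
G30-G32   # other degenerative diseases
G35-G37   # demyelinating diseases
G40-G41   # epilepsy
G43       # migraine
G45-G47   # episodic/paroxysmal and sleep disorders
G50-G59   # nerve/root/plexus disorders
G60-G64   # polyneuropathies
G70-G73   # myoneural junction and muscle diseases
G80-G83   # cerebral palsy and paralytic syndromes
G90-G99

# Chapters VII/VIII — eye and ear (chronic subset)
H25-H28   # cataract and lens disorders
H30-H36   # chorioretinal disorders
H40-H42   # glaucoma
H49-H54   # ocular motility, visual disturbance, blindness
H80-H83   # otosclerosis and inner-ear disorders
H90-H91   # hearing loss

# Chapter IX — circulatory system
I05-I09   # chronic rheumatic heart diseases
I10-I15   # hypertensive diseases
I20       # angina pectoris
I25       # chronic ischemic heart disease
I27-I28   # other pulmonary heart disease, pulmonary vessels
I31       # other pericardial diseases
I34-I37   # nonrheumatic valve disorders
I42-I45   # cardiomyopathy and conduction disorders
I47-I52   # arrhythmias and heart failure
I60-I69   # cerebrovascular diseases
I70-I79   # arteries, arterioles, capillaries
I83       # varicose veins of lower extremities
I87       # other vein disorders

# Chapter X — respiratory system
I95       # hypotension (chronic orthostatic forms)
J30-J35   # chronic rhinitis, sinusitis, tonsil/adenoid disease
J37       # chronic laryngitis
J40-J47   # chronic lower respiratory diseases
J60-J70   # lung diseases due to external agents
J84       # other interstitial pulmonary diseases
J96       # respiratory failure (chronic forms)

# Chapter XI — digestive system
K21       # gastro-esophageal reflux disease
K25-K29   # ulcers and gastritis (chronic forms)
K50-K52   # noninfective enteritis and colitis
K55-K59   # other intestinal diseases (vascular, diverticular, IBS, obstruction)
K70-K77   # liver diseases
K80-K83   # gallbladder and biliary tract
K86       # other diseases of pancreas
K90       # intestinal malabsorption

# Chapter XII — skin (chronic subset)
L40-L45   # papulosquamous disorders
L93-L95   # lupus erythematosus, vasculitis

# Chapter XIII — musculoskeletal system
M05-M19   # inflammatory polyarthropathies and arthrosis
M30-M36   # systemic connective tissue disorders
M40-M54   # dorsopathies including spondylosis
M80-M89   # osteopathies (osteoporosis etc.)

# Chapter XIV — genitourinary system
N00-N08   # glomerular diseases
N11       # chronic tubulo-interstitial nephritis
N18-N19   # renal failure
N25-N28   # other kidney/ureter disorders
N40-N41   # prostate hyperplasia and inflammatory prostate disease
N80-N98   # noninflammatory female genital tract disorders, infertility
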