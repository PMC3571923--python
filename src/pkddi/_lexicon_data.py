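"""Bundled controlled vocabularies.

PK parameter definitions (in vitro and in vivo), tissue-specific transporters,
probe inhibitor/inducer/substrate assignments for the major CYP enzymes and
drug transporters, and the small drug list derived from those probe tables.
All entries follow the FDA drug-interaction guidance vocabulary that PK/DDI
abstracts use.
"""

# ---------------------------------------------------------------------------
# PK parameters.
# rows: (symbol, description, unit, setting, synonyms, priority_rank)
# Priority ranks order parameters when several are reported for one drug pair:
# in vivo AUC > CL > t1/2 > Cmax, in vitro Ki > IC50.
# ---------------------------------------------------------------------------

IN_VITRO_PARAMETERS = [
    ("Km", "Michaelis-Menten constant.", "mg L^-1", "in_vitro",
     ("michaelis-menten constant",), None),
    ("Vmax", "Maximum velocity of the enzyme activity.",
     "mg h^-1 mg^-1 protein", "in_vitro", ("maximum velocity",), None),
    ("CLint", "Intrinsic metabolic clearance: ratio of Vmax and Km.",
     "ml h^-1 mg^-1 protein", "in_vitro", ("intrinsic clearance",), None),
    ("MR", "Parent drug/metabolite concentration ratio.", "", "in_vitro",
     ("metabolic ratio", "urinary ratio", "metabolite ratio"), None),
    ("fm_enzyme",
     "Fraction of systemically available drug converted to a metabolite "
     "through a specific enzyme.", "", "in_vitro",
     ("fraction of metabolism",), None),
    ("Papp", "The apparent permeability of compounds across the monolayer "
     "cells.", "cm/sec", "in_vitro", ("apparent permeability",), None),
    ("Re", "Ratio of basolateral-to-apical over apical-to-basolateral "
     "permeability.", "", "in_vitro",
     ("permeability ratio",), None),
    ("Radioactivity", "Total radioactivity in plasma and bile samples "
     "measured in a liquid scintillation counter.", "dpm/mg protein",
     "in_vitro", ("total radioactivity",), None),
    ("Uptake volume", "Cell-associated radioactivity divided by its "
     "concentration in the incubation medium.", "ul/mg protein", "in_vitro",
     ("uptake volume",), None),
    ("IC50", "Inhibitor concentration that inhibits to 50% of enzyme "
     "activity.", "mg L^-1", "in_vitro",
     ("half-maximal inhibitory concentration", "inhibitory concentration 50"),
     2),
    ("Ki", "Inhibition rate constant for competitive, noncompetitive, and "
     "uncompetitive inhibition.", "mg L^-1", "in_vitro",
     ("inhibition constant", "inhibition rate constant"), 1),
    ("Kdeg", "The natural degradation rate constant for the enzyme.", "h^-1",
     "in_vitro", ("degradation rate constant",), None),
    ("KI", "Inhibitor concentration associated with half-maximal "
     "inactivation in mechanism-based inhibition.", "mg L^-1", "in_vitro",
     ("half-maximal inactivation concentration",), None),
    ("Kinact", "Maximum degradation rate constant at high inhibitor "
     "concentration in mechanism-based inhibition.", "h^-1", "in_vitro",
     ("maximum inactivation rate",), None),
    ("Emax", "Maximum induction rate.", "", "in_vitro",
     ("maximum induction",), None),
    ("EC50", "Inducer concentration associated with the half-maximal "
     "induction.", "mg L^-1", "in_vitro",
     ("half-maximal induction concentration", "half maximal effective concentration"), None),
]

IN_VIVO_PARAMETERS = [
    ("AUC", "Area under the drug concentration time curve.", "mg h L^-1",
     "in_vivo",
     ("area under the concentration curve",
      "area under the concentration-time curve",
      "area under the plasma concentration-time curve",
      "area under the drug concentration time curve"), 1),
    ("AUCinf", "Area under the drug concentration time curve extrapolated "
     "to infinity.", "mg h L^-1", "in_vivo", (), None),
    ("AUCss", "Area under the concentration curve within a dosing interval "
     "at steady state.", "mg h L^-1", "in_vivo", (), None),
    ("AUCt", "Area under the concentration curve from time 0 to t.",
     "mg h L^-1", "in_vivo", (), None),
    ("AUMC", "Area under the first moment of concentration versus time "
     "curve.", "mg^2 h L^-2", "in_vivo", (), None),
    ("AUCR", "AUC ratio (drug interaction parameter).", "", "in_vivo",
     ("auc ratio", "area under the concentration curve ratio"), None),
    ("CL", "Total clearance: proportionality factor relating the rate of "
     "drug elimination to the plasma drug concentration.", "ml h^-1",
     "in_vivo", ("clearance", "total clearance", "oral clearance", "CLoral"), 2),
    ("CLb", "Blood clearance.", "ml h^-1", "in_vivo", ("blood clearance",), None),
    ("CLu", "Unbound clearance.", "ml h^-1", "in_vivo", ("unbound clearance",), None),
    ("CLH", "Hepatic portion of the total clearance.", "ml h^-1", "in_vivo",
     ("hepatic clearance",), None),
    ("CLR", "Renal portion of the total clearance.", "ml h^-1", "in_vivo",
     ("renal clearance",), None),
    ("CLpo", "Total clearance following an oral dose.", "ml h^-1", "in_vivo",
     (), None),
    ("CLIV", "Total clearance following an IV dose.", "ml h^-1", "in_vivo",
     (), None),
    ("CLint", "Intrinsic metabolic clearance: ratio of Vmax and Km.",
     "ml h^-1", "in_vivo", (), None),
    ("CL12", "Inter-compartment distribution clearance.", "ml h^-1",
     "in_vivo", (), None),
    ("CL ratio", "Ratio of the clearance (drug interaction parameter).", "",
     "in_vivo", ("clearance ratio",), None),
    ("Cmax", "Highest drug concentration observed in plasma following an "
     "extravascular dose.", "mg L^-1", "in_vivo",
     ("peak plasma concentration", "peak concentration",
      "maximum plasma concentration", "maximum concentration"), 4),
    ("Cmax ratio", "Ratio of Cmax (drug interaction parameter).", "",
     "in_vivo", (), None),
    ("Css", "Plasma concentration at steady state during constant-rate "
     "infusion.", "mg L^-1", "in_vivo", ("steady state concentration",), None),
    ("Css ratio", "Ratio of Css (drug interaction parameter).", "",
     "in_vivo", (), None),
    ("E", "Extraction ratio: blood clearance over blood flow.", "",
     "in_vivo", ("extraction ratio",), None),
    ("EH", "Hepatic extraction ratio.", "", "in_vivo",
     ("hepatic extraction ratio",), None),
    ("F", "Bioavailability: proportion of the dose reaching systemic "
     "blood.", "", "in_vivo", ("bioavailability",), None),
    ("FG", "Gut-wall bioavailability.", "", "in_vivo", (), None),
    ("FH", "Hepatic bioavailability.", "", "in_vivo", (), None),
    ("FR", "Renal bioavailability.", "", "in_vivo", (), None),
    ("fe", "Fraction of systemically available drug excreted unchanged in "
     "urine.", "", "in_vivo", (), None),
    ("fm", "Fraction of systemically available drug converted to a "
     "metabolite.", "", "in_vivo", (), None),
    ("fu", "Ratio of unbound and total drug concentrations in plasma.", "",
     "in_vivo", ("fraction unbound",), None),
    ("k", "Elimination rate constant.", "h^-1", "in_vivo",
     ("elimination rate constant",), None),
    ("k12", "Distribution rate constant, central to peripheral.", "h^-1",
     "in_vivo", (), None),
    ("k21", "Distribution rate constant, peripheral to central.", "h^-1",
     "in_vivo", (), None),
    ("ka", "Absorption rate constant.", "h^-1", "in_vivo",
     ("absorption rate constant",), None),
    ("ke", "Urinary excretion rate constant.", "h^-1", "in_vivo",
     ("urinary excretion rate constant",), None),
    ("km", "Rate constant for the elimination of a metabolite.", "h^-1",
     "in_vivo", (), None),
    ("Km", "Michaelis-Menten constant.", "mg L^-1", "in_vivo", (), None),
    ("MRT", "Mean time a molecule resides in the body.", "h", "in_vivo",
     ("mean residence time",), None),
    ("Q", "Blood flow.", "L h^-1", "in_vivo", ("blood flow",), None),
    ("QH", "Hepatic blood flow.", "L h^-1", "in_vivo",
     ("hepatic blood flow",), None),
    ("tmax", "Time of the highest observed plasma concentration.", "h",
     "in_vivo", ("time to peak concentration",), None),
    ("t1/2", "Half-life of the drug disposition.", "h", "in_vivo",
     ("half-life", "half life", "elimination half-life",
      "terminal half-life"), 3),
    ("t1/2 ratio", "Half-life ratio (drug interaction parameter).", "",
     "in_vivo", ("half-life ratio",), None),
    ("t1/2,alpha", "Half-life of the fast-phase drug disposition.", "h",
     "in_vivo", (), None),
    ("t1/2,beta", "Half-life of the slow-phase drug disposition.", "h",
     "in_vivo", (), None),
    ("V", "Volume of distribution based on plasma concentration.", "L",
     "in_vivo", ("volume of distribution",), None),
    ("Vb", "Volume of distribution based on blood concentration.", "L",
     "in_vivo", (), None),
    ("V1", "Volume of distribution of the central compartment.", "L",
     "in_vivo", (), None),
    ("V2", "Volume of distribution of the peripheral compartment.", "L",
     "in_vivo", (), None),
    ("Vss", "Volume of distribution at steady state.", "L", "in_vivo",
     (), None),
    ("Vmax", "Maximum rate of metabolism of an enzymatic reaction.",
     "mg h^-1", "in_vivo", (), None),
    ("lambda1", "Fast disposition rate constant, two-compartment model.",
     "h^-1", "in_vivo", (), None),
    ("lambda2", "Slow disposition rate constant, two-compartment model.",
     "h^-1", "in_vivo", (), None),
]

# ---------------------------------------------------------------------------
# Tissue-specific transporters: (gene, aliases, tissues, function)
# ---------------------------------------------------------------------------

TRANSPORTERS = [
    ("ABCB1", ("P-gp", "MDR1"),
     ("intestinal enterocyte", "kidney proximal tubule",
      "hepatocyte (canalicular)", "brain endothelia"), "efflux"),
    ("ABCG2", ("BCRP",),
     ("intestinal enterocyte", "hepatocyte (canalicular)",
      "kidney proximal tubule", "brain endothelia", "placenta", "stem cells",
      "mammary gland (lactating)"), "efflux"),
    ("SLCO1B1", ("OATP1B1", "OATP-C", "OATP2", "LST-1"),
     ("hepatocyte (sinusoidal)",), "uptake"),
    ("SLCO1B3", ("OATP1B3", "OATP-8"), ("hepatocyte (sinusoidal)",),
     "uptake"),
    ("SLC22A2", ("OCT2",), ("kidney proximal tubule",), "uptake"),
    ("SLC22A6", ("OAT1",), ("kidney proximal tubule", "placenta"), "uptake"),
    ("SLC22A8", ("OAT3",),
     ("kidney proximal tubule", "choroid plexus", "brain endothelia"),
     "uptake"),
]

# ---------------------------------------------------------------------------
# Probe inhibitors / inducers / substrates.
# enzyme -> role -> comma-separated drug strings.  Strength tiers for the
# CYP3A inhibitors are intentionally not distinguished; all are role
# "inhibitor".
# ---------------------------------------------------------------------------

CYP_PROBES = {
    "CYP1A2": {
        "inhibitor": (
            "Ciprofloxacin, enoxacin, fluvoxamine, Methoxsalen, mexiletine, "
            "oral contraceptives, phenylpropanolamine, thiabendazole, "
            "vemurafenib, zileuton, acyclovir, allopurinol, caffeine, "
            "cimetidine, daidzein, disulfiram, Echinacea, famotidine, "
            "norfloxacin, propafenone, propranolol, terbinafine, "
            "ticlopidine, verapamil"),
        "inducer": (
            "Montelukast, phenytoin, smokers versus non-smokers, "
            "moricizine, omeprazole, phenobarbital"),
        "substrate": (
            "Alosetron, caffeine, duloxetine, melatonin, ramelteon, "
            "tacrine, tizanidine, theophylline"),
    },
    "CYP2B6": {
        "inhibitor": "Clopidogrel, ticlopidine, prasugrel",
        "inducer": "Efavirenz, rifampin, nevirapine",
        "substrate": "Bupropion, efavirenz",
    },
    "CYP2C8": {
        "inhibitor": "Gemfibrozil, fluvoxamine, ketoconazole, trimethoprim",
        "inducer": "Rifampin",
        "substrate": "Repaglinide, Paclitaxel",
    },
    "CYP2C9": {
        "inhibitor": (
            "Amiodarone, fluconazole, miconazole, oxandrolone, "
            "capecitabine, cotrimoxazole, etravirine, fluvastatin, "
            "fluvoxamine, metronidazole, sulfinpyrazone, tigecycline, "
            "voriconazole, zafirlukast"),
        "inducer": (
            "Carbamazepine, rifampin, aprepitant, bosentan, phenobarbital, "
            "St. John's wort"),
        "substrate": "Celecoxib, Warfarin, phenytoin",
    },
    "CYP2C19": {
        "inhibitor": (
            "Fluconazole, fluvoxamine, ticlopidine, esomeprazole, "
            "fluoxetine, moclobemide, omeprazole, voriconazole, allicin, "
            "armodafinil, carbamazepine, cimetidine, etravirine, "
            "human growth hormone, felbamate, ketoconazole, "
            "oral contraceptives"),
        "inducer": "Rifampin, artemisinin",
        "substrate": "Clobazam, lansoprazole, omeprazole, S-mephenytoin",
    },
    "CYP3A": {
        "inhibitor": (
            "Boceprevir, clarithromycin, conivaptan, grapefruit juice, "
            "indinavir, itraconazole, ketoconazole, lopinavir/ritonavir, "
            "mibefradil, nefazodone, nelfinavir, posaconazole, ritonavir, "
            "saquinavir, telaprevir, telithromycin, voriconazole, "
            "amprenavir, aprepitant, atazanavir, ciprofloxacin, crizotinib, "
            "darunavir/ritonavir, diltiazem, erythromycin, fluconazole, "
            "fosamprenavir, imatinib, verapamil, alprazolam, amiodarone, "
            "amlodipine, atorvastatin, bicalutamide, cilostazol, "
            "cimetidine, cyclosporine, fluoxetine, fluvoxamine, ginkgo, "
            "goldenseal, isoniazid, lapatinib, nilotinib, "
            "oral contraceptives, pazopanib, ranitidine, ranolazine, "
            "tipranavir/ritonavir, ticagrelor, zileuton"),
        "inducer": (
            "Avasimibe, carbamazepine, phenytoin, rifampin, "
            "St. John's wort, bosentan, efavirenz, etravirine, modafinil, "
            "nafcillin, amprenavir, aprepitant, armodafinil, clobazam, "
            "echinacea, pioglitazone, prednisone, rufinamide, vemurafenib"),
        "substrate": (
            "Alfentanil, aprepitant, budesonide, buspirone, conivaptan, "
            "darifenacin, darunavir, dasatinib, dronedarone, eletriptan, "
            "eplerenone, everolimus, felodipine, indinavir, fluticasone, "
            "lopinavir, lovastatin, lurasidone, maraviroc, midazolam, "
            "nisoldipine, quetiapine, saquinavir, sildenafil, simvastatin, "
            "sirolimus, tolvaptan, tipranavir, triazolam, ticagrelor, "
            "vardenafil, astemizole, cisapride, cyclosporine, "
            "dihydroergotamine, ergotamine, fentanyl, pimozide, quinidine, "
            "tacrolimus, terfenadine"),
    },
    "CYP2D6": {
        "inhibitor": (
            "Bupropion, fluoxetine, paroxetine, quinidine, cinacalcet, "
            "duloxetine, terbinafine, amiodarone, celecoxib, clobazam, "
            "cimetidine, desvenlafaxine, diltiazem, diphenhydramine, "
            "echinacea, escitalopram, febuxostat, gefitinib, hydralazine, "
            "hydroxychloroquine, imatinib, methadone, oral contraceptives, "
            "pazopanib, propafenone, ranitidine, ritonavir, sertraline, "
            "telithromycin, verapamil, vemurafenib"),
        "inducer": "",
        "substrate": (
            "Atomoxetine, desipramine, dextromethorphan, metoprolol, "
            "nebivolol, perphenazine, tolterodine, venlafaxine, "
            "Thioridazine, pimozide"),
    },
}

TRANSPORTER_PROBES = {
    "P-gp": {
        "inhibitor": (
            "Amiodarone, azithromycin, captopril, carvedilol, "
            "clarithromycin, conivaptan, cyclosporine, diltiazem, "
            "dronedarone, erythromycin, felodipine, itraconazole, "
            "ketoconazole, lopinavir and ritonavir, quercetin, quinidine, "
            "ranolazine, ticagrelor, verapamil"),
        "inducer": (
            "Avasimibe, carbamazepine, phenytoin, rifampin, "
            "St John's wort, tipranavir/ritonavir"),
        "substrate": (
            "Aliskiren, ambrisentan, colchicine, dabigatran etexilate, "
            "digoxin, everolimus, fexofenadine, imatinib, lapatinib, "
            "maraviroc, nilotinib, posaconazole, ranolazine, saxagliptin, "
            "sirolimus, sitagliptin, talinolol, tolvaptan, topotecan"),
    },
    "BCRP": {
        "inhibitor": "Cyclosporine, elacridar, eltrombopag, gefitinib",
        "inducer": "",
        "substrate": (
            "Methotrexate, mitoxantrone, imatinib, irrinotecan, lapatinib, "
            "rosuvastatin, sulfasalazine, topotecan"),
    },
    "OATP1B1": {
        "inhibitor": (
            "Atazanavir, cyclosporine, eltrombopag, gemfibrozil, lopinavir, "
            "rifampin, ritonavir, saquinavir, tipranavir"),
        "inducer": "",
        "substrate": (
            "Atrasentan, atorvastatin, bosentan, ezetimibe, fluvastatin, "
            "glyburide, SN-38, rosuvastatin, simvastatin acid, "
            "pitavastatin, pravastatin, repaglinide, rifampin, valsartan, "
            "olmesartan"),
    },
    "OATP1B3": {
        "inhibitor": (
            "Atazanavir, cyclosporine, lopinavir, rifampin, ritonavir, "
            "saquinavir"),
        "inducer": "",
        "substrate": (
            "Atorvastatin, rosuvastatin, pitavastatin, telmisartan, "
            "valsartan, olmesartan"),
    },
    "OCT2": {
        "inhibitor": "Cimetidine, quinidine",
        "inducer": "",
        "substrate": (
            "Amantadine, amiloride, cimetidine, dopamine, famotidine, "
            "memantine, metformin, pindolol, procainamide, ranitidine, "
            "varenicline, oxaliplatin"),
    },
    "OAT1": {
        "inhibitor": "Probenecid",
        "inducer": "",
        "substrate": (
            "Adefovir, captopril, furosemide, lamivudine, methotrexate, "
            "oseltamivir, tenofovir, zalcitabine, zidovudine"),
    },
    "OAT3": {
        "inhibitor": "Probenecid, cimetidine, diclofenac",
        "inducer": "",
        "substrate": (
            "Acyclovir, bumetanide, ciprofloxacin, famotidine, furosemide, "
            "methotrexate, zidovudine, oseltamivir acid, penicillin G, "
            "pravastatin, rosuvastatin, sitagliptin"),
    },
}

# Drugs named in the worked-example sentences but absent from the probe
# tables.  canonical -> extra surface forms
EXTRA_DRUGS = {
    "etoposide": (),
    "valspodar": (),
    "perazine": (),
    "ym758": ("YM758",),
    "dpt": ("DPT",),
    "placebo": (),
}

# Extra surface forms for multi-variant probe names.
EXTRA_SURFACE_FORMS = {
    "st. john's wort": ("st john's wort", "st johns wort", "st john’s wort",
                        "st. john’s wort"),
    "st john's wort": ("st. john's wort", "st johns wort", "st john’s wort"),
}
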