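abbreviation,name,kind,units,description
BL,Basilar length,linear,mm,Basion to the anteriormost point of the palate between the incisors (midline ventral view)
SBL,Skull base length,linear,mm,Basion to the posteriormost point of the palate (midline ventral view)
PL,Palatal length,linear,mm,Posteriormost point of the palate to its anteriormost point between the incisors (midline ventral view)
MDL,Maxillary diastemal length,linear,mm,Mesial P2 alveolus to the labio-distal upper I3 alveolus (ventral view)
PW,Premaxillary width,linear,mm,Between left and right labio-distal third-incisor alveoli (ventral view)
SI,Supraorbital interdistance,linear,mm,Between the medial points of the left and right supraorbital foramina (dorsal view)
CRL,Cranial roof length,linear,mm,Occipital protuberance to the nasal-frontal suture (midline dorsal view)
FL,Facial length,linear,mm,Nasal-frontal suture to prosthion (midline dorsal view)
SW,Snout width,linear,mm,Between the anterior ends of the left and right facial crests (dorsal view)
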