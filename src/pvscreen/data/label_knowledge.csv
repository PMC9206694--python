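drug_name,in_label,widely_published,case_reports_published
valproic acid,true,true,true
valpromide,true,true,true
topiramate,true,true,true
asparaginase,true,true,true
fluorouracil,true,true,true
haloperidol,true,true,true
pegaspargase,true,true,true
zonisamide,true,true,true
deferasirox,true,true,true
amphotericin b,true,true,true
carbamazepine,false,true,true
lamotrigine,false,true,true
lenvatinib,false,true,true
phenytoin,false,true,true
clobazam,false,true,true
phenobarbital,false,true,true
glycine,false,false,true
sunitinib,false,false,true
sorafenib,false,false,true
regorafenib,false,false,true
crisantaspase,false,false,true
acetazolamide,false,false,true
paracetamol,false,false,true
capecitabine,false,false,true
ramucirumab,false,false,true
dactinomycin,false,false,true
tacrolimus,false,false,true
gemcitabine,false,false,true
olanzapine,false,false,true
levetiracetam,false,false,true
bevacizumab,false,false,true
lorazepam,false,false,true
stiripentol,false,false,true
lacosamide,false,false,true
oxcarbazepine,false,false,true
risperidone,false,false,true
sofosbuvir,false,false,true
quetiapine,false,false,true
clonazepam,false,false,true
cyclophosphamide,false,false,true
lithium,false,false,true
irinotecan,false,false,true
methotrexate,false,false,true
oxaliplatin,false,false,true
folinic acid,false,false,true
vincristine,false,false,true
mycophenolic acid,false,false,true
basiliximab,false,false,true
cytarabine,false,false,true
daunorubicin,false,false,true
ethosuximide,false,false,true
etoposide,false,false,true
gemtuzumab,false,false,true
melphalan,false,false,true
methylprednisolone,false,false,true
mitoxantrone,false,false,true
ondansetron,false,false,true
propofol,false,false,true
ribavirin,false,false,true
rovalpituzumab tesirine,false,false,true
trihexyphenidyl,false,false,true
eltrombopag,false,false,false
cannabidiol,false,false,false
tolvaptan,false,false,false
ciclosporin,false,false,false
hydrocortisone,false,false,false
prednisone,false,false,false
citalopram,false,false,false
antithymocyte immunoglobulin,false,false,false
dexamethasone,false,false,false
oxazepam,false,false,false
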