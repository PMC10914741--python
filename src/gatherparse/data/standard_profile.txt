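gbifID
datasetKey
occurrenceID
kingdom
phylum
class
order
family
genus
species
infraspecificEpithet
taxonRank
scientificName
scientificNameAuthorship
verbatimScientificName
taxonKey
speciesKey
countryCode
locality
municipality
county
stateProvince
occurrenceStatus
individualCount
decimalLatitude
decimalLongitude
coordinateUncertaintyInMeters
coordinatePrecision
elevation
elevationAccuracy
habitat
fieldNotes
eventDate
day
month
year
verbatimEventDate
basisOfRecord
institutionCode
collectionCode
catalogNumber
recordNumber
recordedBy
identifiedBy
dateIdentified
typeStatus
establishmentMeans
license
rightsHolder
datasetName
publishingOrgKey
lastInterpreted
mediaType
issue
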